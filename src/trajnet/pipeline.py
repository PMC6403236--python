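"""Config-driven orchestration of the full analysis workflow.

Given a set of labelled complexes (e.g. wild-type vs mutants, apo vs
ligand-bound), each with one or more simulation runs, the pipeline computes
per-run stability metrics (RMSD, RMSF, Rg, SASA), hydrogen-bond counts,
minimum and centre-of-mass distances, interaction-energy decompositions,
pooled essential-dynamics results (eigensystem, PC projections,
free-energy landscape, representative structure), a residue interaction
network with betweenness centrality, and cross-complex comparisons
(covariance overlap / RMSIP matrices and differential-centrality tables).

Outputs are CSV files plus annotated PDB structures under a report
directory; re-running with the same config and seed reproduces every CSV
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .energetics import interaction_energy_series
from .essential_dynamics import (
    build_covariance,
    covariance_overlap,
    cumulative_variance,
    fel,
    project,
    representative_frame,
    rmsip,
)
from .geometry import (
    com_distance,
    min_distance,
    radius_of_gyration,
    rmsd_series,
    rmsf,
    sasa_series,
)
from .hbond import HBondCriteria, detect_hbonds, infer_donors_acceptors
from .network import (
    betweenness,
    build_rin,
    differential_centrality,
    map_centrality_to_structure,
    select_central,
)
from .structio import (
    NonbondedParams,
    Selection,
    Trajectory,
    TrajnetError,
    load_params,
    read_pdb,
    resolve_selection,
    write_params,
    write_pdb,
)
from .synthetic_data import (
    ComplexSpec,
    PlantedHBond,
    make_gaussian_trajectory,
    make_params_fixture,
    make_toy_complex,
    random_fluctuation_spec,
    write_truth,
)

logger = logging.getLogger("trajnet.pipeline")


class PipelineError(TrajnetError):
    pass


@dataclass
class ComplexConfig:
    label: str
    trajectories: list[str]
    params: str | None = None
    timestep_ps: float = 10.0
    selections: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    """Structured pipeline configuration; every default is overridable."""

    complexes: list[ComplexConfig]
    reference: str | None = None
    window_ns: float = 60.0
    hbond_da_cutoff: float = 0.35
    hbond_angle_cutoff: float = 30.0
    energy_cutoff: float | None = None
    pca_k: int = 10
    fel_bins: int = 32
    temperature_K: float = 300.0
    contact_cutoff: float = 0.7
    centrality_threshold: float = 0.1
    differential_threshold: float = 0.05
    centrality_mode: str = "unweighted"
    sasa_stride: int = 10
    sasa_n_points: int = 960
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [c.label for c in self.complexes]
        if len(labels) != len(set(labels)):
            raise PipelineError("complex labels must be unique")
        if self.reference is not None and self.reference not in labels:
            raise PipelineError(
                f"reference label {self.reference!r} not among complexes"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        complexes = [
            ComplexConfig(
                label=c["label"],
                trajectories=list(c["trajectories"]),
                params=c.get("params"),
                timestep_ps=float(c.get("timestep_ps", 10.0)),
                selections=dict(c.get("selections", {})),
            )
            for c in d.get("complexes", [])
        ]
        kwargs = {
            k: d[k]
            for k in (
                "reference",
                "window_ns",
                "hbond_da_cutoff",
                "hbond_angle_cutoff",
                "energy_cutoff",
                "pca_k",
                "fel_bins",
                "temperature_K",
                "contact_cutoff",
                "centrality_threshold",
                "differential_threshold",
                "centrality_mode",
                "sasa_stride",
                "sasa_n_points",
                "seed",
            )
            if k in d
        }
        return cls(complexes=complexes, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "complexes": [
                {
                    "label": c.label,
                    "trajectories": c.trajectories,
                    "params": c.params,
                    "timestep_ps": c.timestep_ps,
                    "selections": c.selections,
                }
                for c in self.complexes
            ],
            "reference": self.reference,
            "window_ns": self.window_ns,
            "hbond_da_cutoff": self.hbond_da_cutoff,
            "hbond_angle_cutoff": self.hbond_angle_cutoff,
            "energy_cutoff": self.energy_cutoff,
            "pca_k": self.pca_k,
            "fel_bins": self.fel_bins,
            "temperature_K": self.temperature_K,
            "contact_cutoff": self.contact_cutoff,
            "centrality_threshold": self.centrality_threshold,
            "differential_threshold": self.differential_threshold,
            "centrality_mode": self.centrality_mode,
            "sasa_stride": self.sasa_stride,
            "sasa_n_points": self.sasa_n_points,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_CSV_FLOAT = "%.10g"


def _write_series(series, path: Path) -> None:
    pd.DataFrame({"time_ps": series.times_ps, "value": series.values}).to_csv(
        path, index=False, float_format=_CSV_FLOAT
    )


def _write_profile(profile, path: Path) -> None:
    rows = []
    for key, v in zip(profile.keys, profile.values):
        chain, resid, resname = key
        rows.append({"chain": chain, "resid": resid, "resname": resname, "value": v})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_CSV_FLOAT)


def _hbond_counts_multi(traj, donors, criteria, group_pairs, window):
    """Per-frame inter-group H-bond counts for several group pairs at once."""
    chains_sets = {
        name: (frozenset(map(int, a.indices)), frozenset(map(int, b.indices)))
        for name, (a, b) in group_pairs.items()
    }
    counts = {name: np.empty(traj.n_frames) for name in group_pairs}
    for f in range(traj.n_frames):
        bonds = detect_hbonds(traj.coords[f], donors, criteria)
        for name, (sa, sb) in chains_sets.items():
            n = 0
            for b in bonds:
                if (b.donor in sa and b.acceptor in sb) or (
                    b.donor in sb and b.acceptor in sa
                ):
                    n += 1
            counts[name][f] = n
    stats = {
        name: (float(c[window].mean()), float(c[window].std()))
        for name, c in counts.items()
    }
    return counts, stats


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full analysis workflow and write the report tree.

    Raises :class:`PipelineError` naming the stage and complex on failure;
    partial outputs are kept next to a ``FAILED_<stage>`` marker file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_pipeline(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_pipeline(config: PipelineConfig, outdir: Path) -> Path:
    logger.info("trajnet %s", __version__)
    logger.info("config hash %s", config.config_hash())
    logger.info("seed %d", config.seed)

    criteria = HBondCriteria(config.hbond_da_cutoff, config.hbond_angle_cutoff)
    window_ps = config.window_ns * 1000.0
    models = {}
    tables = {}
    rep_structures = {}

    def _stage(label: str, name: str, cdir: Path, fn):
        try:
            return fn()
        except Exception as exc:
            (cdir / f"FAILED_{name}").write_text(str(exc) + "\n")
            raise PipelineError(
                f"stage {name!r} failed for complex {label!r}: {exc}"
            ) from exc

    for cc in config.complexes:
        cdir = outdir / cc.label
        cdir.mkdir(exist_ok=True)
        logger.info("complex %s: %d run(s)", cc.label, len(cc.trajectories))
        runs = _stage(
            cc.label,
            "load",
            cdir,
            lambda: [read_pdb(p, timestep_ps=cc.timestep_ps) for p in cc.trajectories],
        )
        top = runs[0].topology
        sel = {
            name: resolve_selection(top, expr)
            for name, expr in cc.selections.items()
        }
        analysis = sel.get("analysis") or resolve_selection(top, "backbone")
        chain_a = sel.get("chain_a")
        chain_b = sel.get("chain_b")
        ligand = sel.get("ligand")
        protein = sel.get("protein") or analysis
        params = (
            load_params(cc.params, top) if cc.params else None
        )
        donors = infer_donors_acceptors(runs[0])
        energy_rows = []
        run_windows = []
        for r, traj in enumerate(runs, start=1):
            rdir = cdir / f"run{r}"
            rdir.mkdir(exist_ok=True)
            widx = traj.last_window(window_ps)
            run_windows.append(widx)

            def _series_stage():
                _write_series(rmsd_series(traj, analysis), rdir / "rmsd.csv")
                _write_profile(
                    rmsf(traj, analysis, frame_window=widx), rdir / "rmsf.csv"
                )
                _write_series(radius_of_gyration(traj, protein), rdir / "rg.csv")
                _write_series(
                    sasa_series(
                        traj,
                        protein,
                        stride=config.sasa_stride,
                        n_points=config.sasa_n_points,
                    ),
                    rdir / "sasa.csv",
                )

            _stage(cc.label, "stability", rdir, _series_stage)

            def _hbond_stage():
                pairs = {}
                if ligand is not None and chain_a is not None:
                    pairs["chainA_ligand"] = (chain_a, ligand)
                if ligand is not None and chain_b is not None:
                    pairs["chainB_ligand"] = (chain_b, ligand)
                if chain_a is not None and chain_b is not None:
                    pairs["chainA_chainB"] = (chain_a, chain_b)
                if not pairs:
                    return
                counts, stats = _hbond_counts_multi(
                    traj, donors, criteria, pairs, widx
                )
                rows = []
                for name, c in counts.items():
                    pd.DataFrame({"time_ps": traj.times_ps, "count": c}).to_csv(
                        rdir / f"hbond_{name}.csv",
                        index=False,
                        float_format=_CSV_FLOAT,
                    )
                    rows.append(
                        {
                            "pair": name,
                            "mean": stats[name][0],
                            "sd": stats[name][1],
                        }
                    )
                pd.DataFrame(rows).to_csv(
                    rdir / "hbond_summary.csv", index=False, float_format=_CSV_FLOAT
                )

            _stage(cc.label, "hbonds", rdir, _hbond_stage)

            def _distance_stage():
                if chain_a is not None and chain_b is not None:
                    _write_series(
                        com_distance(traj, chain_a, chain_b), rdir / "comdist.csv"
                    )
                if ligand is not None and chain_b is not None:
                    _write_series(
                        min_distance(traj, chain_b, ligand), rdir / "mindist.csv"
                    )

            _stage(cc.label, "distances", rdir, _distance_stage)

            def _energy_stage():
                if params is None:
                    return
                pairs = []
                if ligand is not None and protein is not None:
                    pairs.append(("protein", "ligand", protein, ligand))
                if chain_a is not None and chain_b is not None:
                    pairs.append(("chainA", "chainB", chain_a, chain_b))
                for la, lb, sa, sb in pairs:
                    series, row = interaction_energy_series(
                        traj,
                        sa,
                        sb,
                        params,
                        cutoff=config.energy_cutoff,
                        window=widx,
                        labels=(la, lb),
                        run=f"run{r}",
                    )
                    pd.DataFrame(
                        {
                            "time_ps": series.times_ps,
                            "coulomb": series.coulomb,
                            "lj": series.lennard_jones,
                            "total": series.total,
                        }
                    ).to_csv(
                        rdir / f"energy_{la}_{lb}.csv",
                        index=False,
                        float_format=_CSV_FLOAT,
                    )
                    energy_rows.append(row)

            _stage(cc.label, "energy", rdir, _energy_stage)

        if energy_rows:
            pd.DataFrame(
                [
                    {
                        "group_a": row.group_a,
                        "group_b": row.group_b,
                        "run": row.run,
                        "mean_coulomb": row.mean_coulomb,
                        "mean_lj": row.mean_lennard_jones,
                        "mean_total": row.mean_total,
                        "error": row.error,
                    }
                    for row in energy_rows
                ]
            ).to_csv(cdir / "energy_table.csv", index=False, float_format=_CSV_FLOAT)

        # --- pooled essential dynamics ---------------------------------- #
        pdir = cdir / "pca"
        pdir.mkdir(exist_ok=True)

        def _pca_stage():
            window_trajs = [
                Trajectory(t.topology, t.coords[w], t.timestep_ps, t.time_origin_ps)
                for t, w in zip(runs, run_windows)
            ]
            frame_map = [
                (ri, int(f))
                for ri, w in enumerate(run_windows)
                for f in w
            ]
            model = build_covariance(window_trajs, analysis)
            models[cc.label] = model
            k = min(config.pca_k, model.n_dof)
            evals = model.eigenvalues
            cum = np.cumsum(evals) / model.trace if model.trace > 0 else evals * 0
            pd.DataFrame(
                {
                    "index": np.arange(1, evals.size + 1),
                    "value": evals,
                    "cumulative": cum,
                }
            ).to_csv(pdir / "eigenvalues.csv", index=False, float_format=_CSV_FLOAT)
            proj = project(window_trajs, model, k)
            cols = {"frame": np.arange(proj.scores.shape[0])}
            for i in range(k):
                cols[f"pc{i + 1}"] = proj.scores[:, i]
            pd.DataFrame(cols).to_csv(
                pdir / "projections.csv", index=False, float_format=_CSV_FLOAT
            )
            grid = fel(
                proj,
                0,
                1,
                n_bins=config.fel_bins,
                temperature_K=config.temperature_K,
            )
            finite = grid.free_energy[np.isfinite(grid.free_energy)]
            cap = float(finite.max()) + 1.0 if finite.size else 1.0
            rows = []
            for bi in range(grid.counts.shape[0]):
                for bj in range(grid.counts.shape[1]):
                    occupied = grid.counts[bi, bj] > 0
                    dg = grid.free_energy[bi, bj] if occupied else cap
                    rows.append(
                        {
                            "i": bi,
                            "j": bj,
                            "center_i": 0.5 * (grid.xedges[bi] + grid.xedges[bi + 1]),
                            "center_j": 0.5 * (grid.yedges[bj] + grid.yedges[bj + 1]),
                            "count": int(grid.counts[bi, bj]),
                            "dG": dg,
                            "occupied": int(occupied),
                        }
                    )
            pd.DataFrame(rows).to_csv(
                pdir / "fel.csv", index=False, float_format=_CSV_FLOAT
            )
            rep = representative_frame(grid, proj)
            ri, fi = frame_map[rep]
            rep_struct = runs[ri].frame(fi)
            rep_structures[cc.label] = rep_struct
            write_pdb(
                Trajectory(top, rep_struct.coords[None]),
                pdir / "representative.pdb",
            )

        _stage(cc.label, "pca", pdir, _pca_stage)

        # --- residue interaction network -------------------------------- #
        ndir = cdir / "network"
        ndir.mkdir(exist_ok=True)

        def _network_stage():
            rep_struct = rep_structures[cc.label]
            bonds = detect_hbonds(rep_struct.coords, donors, criteria)
            rin = build_rin(rep_struct, bonds, config.contact_cutoff)
            edges = [
                {
                    "chainA": u[0],
                    "residA": u[1],
                    "chainB": v[0],
                    "residB": v[1],
                    "distance_nm": data["distance_nm"],
                    "hbond_weight": data["hbond_weight"],
                }
                for u, v, data in rin.graph.edges(data=True)
            ]
            pd.DataFrame(edges).to_csv(
                ndir / "rin_edges.csv", index=False, float_format=_CSV_FLOAT
            )
            table = betweenness(rin, mode=config.centrality_mode)
            tables[cc.label] = table
            central = select_central(table, config.centrality_threshold)
            flagged = set(central)
            pd.DataFrame(
                [
                    {
                        "chain": nk[0],
                        "resid": nk[1],
                        "resname": table.resnames.get(nk, "UNK"),
                        "C_B": table[nk],
                        "flagged": int(nk in flagged),
                    }
                    for nk in table.nodes()
                ]
            ).to_csv(ndir / "centrality.csv", index=False, float_format=_CSV_FLOAT)
            map_centrality_to_structure(
                rep_struct, table, ndir / "centrality.pdb", central
            )

        _stage(cc.label, "network", ndir, _network_stage)

    # --- cross-complex comparisons -------------------------------------- #
    xdir = outdir / "cross"
    xdir.mkdir(exist_ok=True)
    labels = [c.label for c in config.complexes]
    if len(labels) > 1:
        over_rows = []
        rmsip_rows = []
        for i, la in enumerate(labels):
            for lb in labels[i + 1 :]:
                k = min(config.pca_k, models[la].n_dof, models[lb].n_dof)
                over_rows.append(
                    {
                        "label_a": la,
                        "label_b": lb,
                        "normalized_overlap": covariance_overlap(
                            models[la], models[lb], k
                        ),
                    }
                )
                r, _ = rmsip(models[la], models[lb], k)
                rmsip_rows.append({"label_a": la, "label_b": lb, "rmsip": r})
        pd.DataFrame(over_rows).to_csv(
            xdir / "overlap.csv", index=False, float_format=_CSV_FLOAT
        )
        pd.DataFrame(rmsip_rows).to_csv(
            xdir / "rmsip.csv", index=False, float_format=_CSV_FLOAT
        )
    if config.reference is not None and len(labels) > 1:
        ref_table = tables[config.reference]
        alt_labels = [l for l in labels if l != config.reference]
        flagged_sets = []
        for al in alt_labels:
            flagged, delta, _ = differential_centrality(
                ref_table, tables[al], config.differential_threshold
            )
            flagged_sets.append(set(flagged))
            pd.DataFrame(
                [
                    {
                        "chain": nk[0],
                        "resid": nk[1],
                        "delta": delta[nk],
                        "flagged": int(nk in set(flagged)),
                    }
                    for nk in sorted(delta)
                ]
            ).to_csv(
                xdir / f"diffcent_{al}.csv", index=False, float_format=_CSV_FLOAT
            )
        common = set.intersection(*flagged_sets) if flagged_sets else set()
        pd.DataFrame(
            [{"chain": c, "resid": r} for c, r in sorted(common)],
            columns=["chain", "resid"],
        ).to_csv(xdir / "common_residues.csv", index=False, float_format=_CSV_FLOAT)
    logger.info("pipeline complete")
    return outdir


# --------------------------------------------------------------------------- #
# Synthetic study generation
# --------------------------------------------------------------------------- #


def default_planted_bonds(
    n_chain_ligand: int = 5, n_dimer: int = 1, mutant_shift: int = 0
) -> list[PlantedHBond]:
    """A study-like planting: ``n_chain_ligand`` bonds from each protein
    chain to one ligand strand (N-/C-terminal sites) plus ``n_dimer``
    chain A ↔ chain B bonds at the dimer interface.  ``mutant_shift``
    offsets the donor residues, emulating a mutation-induced rearrangement
    of the contact pattern without changing the architecture."""
    bonds: list[PlantedHBond] = []
    for i in range(n_chain_ligand):
        bonds.append(
            PlantedHBond(("A", 2 + i + mutant_shift), ("R", 1 + i), "N-terminal")
        )
        bonds.append(
            PlantedHBond(("B", 2 + i + mutant_shift), ("S", 1 + i), "C-terminal")
        )
    for i in range(n_dimer):
        bonds.append(PlantedHBond(("A", 12 + i), ("B", 12 + i), "dimer"))
    return bonds


def generate_synthetic_study(
    outdir: str | Path,
    labels: tuple[str, ...] = ("wt", "mutant"),
    n_runs: int = 3,
    n_frames: int = 500,
    seed: int = 0,
    window_ns: float | None = None,
    identical: bool = False,
    mode_variances: tuple[float, ...] = (0.09, 0.03, 0.01),
    noise_sigma: float = 0.003,
) -> Path:
    """Generate a complete synthetic study and its pipeline config.

    For each label a toy complex is built (``identical`` reuses the same
    geometry seed and planting for every label, useful as a null study),
    ``n_runs`` planted-mode Gaussian trajectories are sampled and written
    as multi-model PDB files together with a random nonbonded parameter
    table and a planted-truth JSON sidecar.  Default mode variances keep
    per-atom fluctuations near 0.02 nm so the planted contact geometry
    persists through the run, as in a converged stable complex.  Returns
    the config path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    complexes = []
    for ci, label in enumerate(labels):
        cdir = outdir / label
        cdir.mkdir(exist_ok=True)
        geom_seed = seed if identical else seed + 1000 * ci
        shift = 0 if (identical or ci == 0) else ci
        spec = ComplexSpec(
            planted_hbonds=default_planted_bonds(mutant_shift=shift),
            seed=geom_seed,
        )
        base, truth = make_toy_complex(spec)
        write_truth(truth, cdir / "truth.json")
        params = make_params_fixture(base.frame(0), "random", seed=geom_seed + 7)
        write_params(params, base.topology, cdir / "params.tsv")
        traj_paths = []
        for r in range(n_runs):
            run_seed = geom_seed + 17 + r if not identical else seed + 17 + r
            fspec = random_fluctuation_spec(
                base.frame(0),
                variances=mode_variances,
                n_frames=n_frames,
                noise_sigma=noise_sigma,
                seed=run_seed,
            )
            traj = make_gaussian_trajectory(base.frame(0), fspec)
            p = cdir / f"run{r + 1}.pdb"
            write_pdb(traj, p)
            traj_paths.append(str(p))
        complexes.append(
            {
                "label": label,
                "trajectories": traj_paths,
                "params": str(cdir / "params.tsv"),
                "timestep_ps": 10.0,
                "selections": {
                    "analysis": "backbone and chain A B",
                    "protein": "chain A B",
                    "chain_a": "chain A",
                    "chain_b": "chain B",
                    "ligand": "chain R S",
                },
            }
        )
    if window_ns is None:
        # Last 60% of each run, in the spirit of discarding equilibration.
        window_ns = 0.6 * n_frames * 10.0 / 1000.0
    cfg = {
        "complexes": complexes,
        "reference": labels[0],
        "window_ns": window_ns,
        "seed": seed,
    }
    cfg_path = outdir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return cfg_path
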