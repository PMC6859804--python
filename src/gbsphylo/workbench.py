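"""Parameter-grid sweeps and MinError / MaxResol configuration selection.

The exploratory phase of a GBS study assembles the same reads under a grid of
pipeline settings (data type, majority-rule base calling, minimum sample
coverage, clustering threshold) and asks two questions of every assembly:
how large are the replicate-based error rates, and how well resolved are the
resulting trees?  The two answers pull in opposite directions, and the
workflow ends by naming one configuration per criterion:

* MinError  — lexicographic minimum on (allele error, SNP error), ties broken
  by lower locus error and then by more loci;
* MaxResol  — maximum mean resolution across the available tree-method
  columns, ties broken by more parsimony-informative sites.

Here the sweep is driven end-to-end on synthetic data: one ground truth is
simulated per sweep and each configuration corrupts it with its own error
specification, filters by minimum taxon coverage, and reports assembly
statistics, error rates and (optionally) NJ-bootstrap resolution.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import loci as loci_mod
from . import replication, simulate, trees

logger = logging.getLogger("gbsphylo")

DATA_TYPES = ("merged", "unmerged")
CLUSTERING = ("85", "90", "90_85")
MRB_ALLOWED_COVERAGE = (5, 10)


@dataclass(frozen=True)
class Configuration:
    """One exploratory assembly configuration (data type excluded)."""

    majority_rule: bool
    min_sample_cov: int
    clust_threshold: str

    @property
    def label(self) -> str:
        mrb = "mrb" if self.majority_rule else "nomrb"
        return f"{mrb}_cov{self.min_sample_cov}_c{self.clust_threshold}"


@dataclass
class ConfigGrid:
    """Axes of the exploratory grid, with the majority-rule constraint.

    Majority-rule base calling applies to low-depth sites and therefore only
    combines with minimum sample coverages in {5, 10}.
    """

    data_types: tuple[str, ...] = DATA_TYPES
    majority_rule: tuple[bool, ...] = (False, True)
    min_sample_cov: tuple[int, ...] = (2, 5, 10)
    clust_thresholds: tuple[str, ...] = CLUSTERING
    min_taxon_cov: tuple[float, ...] = (0.15,)

    def __post_init__(self) -> None:
        for dt in self.data_types:
            if dt not in DATA_TYPES:
                raise ValueError(f"unknown data type {dt!r}")
        if not (self.data_types and self.majority_rule and self.min_sample_cov
                and self.clust_thresholds):
            raise ValueError("all grid axes must be non-empty")


def enumerate_grid(grid: ConfigGrid) -> list[Configuration]:
    """Deterministic configuration enumeration honoring the MRB constraint."""
    out = []
    for mrb in grid.majority_rule:
        for cov in grid.min_sample_cov:
            if mrb and cov not in MRB_ALLOWED_COVERAGE:
                continue
            for clust in grid.clust_thresholds:
                out.append(Configuration(mrb, cov, clust))
    if not out:
        raise ValueError("grid enumeration is empty")
    return out


def enumerate_assemblies(grid: ConfigGrid) -> list[tuple[str, Configuration]]:
    """(data type, configuration) pairs — one per assembly run."""
    return [(dt, cfg) for dt in grid.data_types for cfg in enumerate_grid(grid)]


# ---------------------------------------------------------------------------
# sweep


def _stable_seed(base_seed: int, label: str) -> int:
    return (base_seed * 1_000_003 + zlib.crc32(label.encode())) % (2**31 - 1)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    sim = cfg.get("simulation")
    if not isinstance(sim, dict):
        raise ValueError("config missing 'simulation' section")
    for key in ("n_taxa", "n_loci", "locus_length", "mu"):
        if key not in sim:
            raise ValueError(f"simulation section missing {key!r}")
    if "seed" not in cfg:
        raise ValueError("config must set an explicit 'seed' (no wall-clock seeding)")
    em = cfg.get("error_model", {})
    if "default" not in em:
        raise ValueError("error_model must provide a 'default' spec")


def _spec_from(params: dict) -> simulate.ErrorSpec:
    allowed = {"dropout", "seq_error", "het_collapse", "geno_swap"}
    unknown = set(params) - allowed - {"n_loci"}
    if unknown:
        raise ValueError(f"unknown error-spec fields: {sorted(unknown)}")
    return simulate.ErrorSpec(**{k: v for k, v in params.items() if k in allowed})


def run_sweep(cfg: dict | str, seed: int | None = None,
              compute_trees: bool | None = None) -> pd.DataFrame:
    """Run every grid configuration against one synthetic ground truth.

    Returns one report row per configuration; fully reproducible for a fixed
    seed, and rows are independent (each configuration derives its own child
    seed from its label).  A failing configuration is logged and skipped.
    """
    if isinstance(cfg, str):
        cfg = load_config(cfg)
    else:
        _validate_config(cfg)
    sim = cfg["simulation"]
    base_seed = int(seed if seed is not None else cfg["seed"])
    grid_cfg = cfg.get("grid", {})
    grid = ConfigGrid(
        data_types=tuple(grid_cfg.get("data_types", ("merged",))),
        majority_rule=tuple(grid_cfg.get("majority_rule", (False, True))),
        min_sample_cov=tuple(grid_cfg.get("min_sample_cov", (2, 5, 10))),
        clust_thresholds=tuple(str(c) for c in grid_cfg.get("clust_thresholds", CLUSTERING)),
        min_taxon_cov=tuple(grid_cfg.get("min_taxon_cov", (0.15,))),
    )
    em = cfg.get("error_model", {"default": {}})
    if compute_trees is None:
        compute_trees = bool(cfg.get("trees", {}).get("enabled", False))
    n_bootstrap = int(cfg.get("trees", {}).get("n_bootstrap", 50))
    resolution_threshold = float(cfg.get("trees", {}).get("bs_threshold", 70.0))

    t0 = time.perf_counter()
    tree = simulate.simulate_species_tree(
        int(sim["n_taxa"]), float(sim.get("birth_rate", 1.0)), base_seed
    )
    truth = simulate.evolve_loci(
        tree, int(sim["n_loci"]), int(sim["locus_length"]),
        float(sim["mu"]), float(sim.get("het", 0.0)), base_seed + 1,
    )
    n_pairs = int(sim.get("n_replicate_pairs", 3))
    pairing = [(t, f"{t}-A", f"{t}-B") for t in truth.taxa[:n_pairs]]
    logger.info("simulated truth: %d taxa, %d loci (%.2fs)",
                len(truth.taxa), len(truth.loci), time.perf_counter() - t0)

    rows = []
    multi_mtc = len(grid.min_taxon_cov) > 1
    for data_type, config in enumerate_assemblies(grid):
        base_label = f"{data_type}_{config.label}"
        for mtc in grid.min_taxon_cov:
            label = base_label + (f"_mtc{int(round(mtc * 100))}" if multi_mtc else "")
            try:
                rows.append(
                    _run_one(base_label, label, data_type, config, mtc, truth,
                             pairing, em, base_seed, compute_trees, n_bootstrap,
                             resolution_threshold,
                             float(sim.get("background_dropout", 0.0)))
                )
            except Exception as exc:  # row failure must not abort the sweep
                logger.error("configuration %s (mtc=%s) failed: %s", label, mtc, exc)
    return pd.DataFrame(rows)


def _run_one(base_label, label, data_type, config, mtc, truth, pairing, em,
             base_seed, compute_trees, n_bootstrap, bs_threshold,
             background_dropout):
    t0 = time.perf_counter()
    params = dict(em.get("default", {}))
    params.update(em.get("per_label", {}).get(base_label, {}))
    spec = _spec_from(params)
    child_seed = _stable_seed(base_seed, base_label)

    use_truth = truth
    if "n_loci" in params:
        k = int(params["n_loci"])
        use_truth = simulate.TrueGenotypes(
            truth.taxa, truth.loci[:k], truth.mu, truth.het, truth.seed
        )
    assembly, _ = simulate.corrupt_assembly(
        use_truth, spec, pairing, child_seed, background_dropout
    )
    filtered = loci_mod.filter_min_taxon_coverage(assembly, mtc)
    st = loci_mod.assembly_stats(filtered)
    report = replication.error_report(filtered, pairing)

    row = {
        "label": label,
        "data_type": data_type,
        "majority_rule": config.majority_rule,
        "min_sample_cov": config.min_sample_cov,
        "clust_threshold": config.clust_threshold,
        "min_taxon_cov": mtc,
        "n_loci": st.n_loci,
        "total_bp": st.total_bp,
        "n_snps": st.n_snps,
        "n_pis": st.n_pis,
        "n_singletons": st.n_singletons,
        "pct_missing": round(st.pct_missing, 2),
    }
    for col in replication.RATE_COLUMNS:
        row[col] = round(float(report.mean.get(col, np.nan)), 4)

    if compute_trees:
        matrix, _ = loci_mod.concatenate(filtered)
        nj = trees.nj_bootstrap_tree(matrix, n_bootstrap=n_bootstrap,
                                     seed=child_seed + 1)
        row["nj_resolution"] = round(
            trees.resolution_quotient(nj, bs_threshold), 4
        )
    logger.info("configuration %s (mtc=%s) done in %.2fs", label, mtc,
                time.perf_counter() - t0)
    return row


# ---------------------------------------------------------------------------
# selection


def select_configurations(report: pd.DataFrame) -> tuple[str, str]:
    """(MinError label, MaxResol label) from a sweep report.

    MinError: lexicographic minimum on (allele_error, snp_error), ties broken
    by lower locus_error, then by more loci.  MaxResol: maximum mean over the
    ``*resolution*`` columns, ties broken by more PIS.  Row order never
    matters.
    """
    required = {"allele_error", "snp_error"}
    if not required <= set(report.columns):
        raise ValueError(f"report missing columns {sorted(required - set(report.columns))}")
    res_cols = [c for c in report.columns if "resolution" in c]
    if not res_cols:
        raise ValueError("report has no resolution column")
    if report[res_cols].isna().all(axis=None):
        raise ValueError("all rows missing resolution values")

    df = report.copy()
    df["_resmean"] = df[res_cols].mean(axis=1, skipna=True)
    min_error = df.sort_values(
        by=["allele_error", "snp_error", "locus_error", "n_loci", "label"],
        ascending=[True, True, True, False, True],
        kind="mergesort",
    ).iloc[0]["label"]
    max_resol = df.sort_values(
        by=["_resmean", "n_pis", "label"],
        ascending=[False, False, True],
        kind="mergesort",
    ).iloc[0]["label"]
    return str(min_error), str(max_resol)
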