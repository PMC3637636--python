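"""Empirical false/true-positive-rate benchmark across scenarios and methods.

For each (scenario, outlier-status) cell the harness simulates
replicate datasets, runs every requested stratification method, and
pools the per-SNP p-values of each testing-SNP category into an
empirical rejection rate at the nominal level (0.01 by default).  For
null categories (random and differentiated SNPs) the rate is a false
positive rate; for causal SNPs it is a true positive rate.  Rates are
pooled over datasets, which coincides with averaging per-dataset rates
when every dataset contributes the same number of SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assoc import METHODS, run_method
from .simulate import (
    AdmixedScenario,
    DiscreteScenario,
    OutlierInjectionConfig,
    inject_dataset_outliers,
    scenario,
    simulate_scenario,
)

__all__ = ["BenchmarkTable", "empirical_rates", "run_benchmark", "METHOD_ORDER"]

log = logging.getLogger(__name__)

#: column order mirroring the comparison tables
METHOD_ORDER = ("trend", "gc", "pca", "mds", "rpca_rhm", "rpca_pp")


@dataclass
class BenchmarkTable:
    """Long-format benchmark results plus provenance.

    ``table`` has one row per (scenario, outliers, snp_type, method)
    cell with the empirical rate in percent and the pooled test count.
    """

    table: pd.DataFrame
    alpha: float
    n_datasets: int
    seed: int
    failures: list = field(default_factory=list)

    def rate(self, scen: str, outliers: bool, snp_type: str, method: str) -> float:
        t = self.table
        row = t[
            (t.scenario == scen)
            & (t.outliers == outliers)
            & (t.snp_type == snp_type)
            & (t.method == method)
        ]
        if row.empty:
            raise KeyError((scen, outliers, snp_type, method))
        return float(row.rate.iloc[0])

    def pivot(self) -> pd.DataFrame:
        """Wide table: rows (scenario, outliers, snp_type), method columns."""
        return self.table.pivot_table(
            index=["scenario", "outliers", "snp_type"],
            columns="method",
            values="rate",
        )[list(c for c in METHOD_ORDER if c in set(self.table.method))]


def empirical_rates(p_values, alpha: float = 0.01) -> float:
    """Percent of tests rejected at the nominal level, pooled over inputs."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return 100.0 * float(np.mean(p < alpha))


def _resolve_scenario(spec, overrides):
    if isinstance(spec, (DiscreteScenario, AdmixedScenario)):
        scen = spec
        if overrides:
            scen = replace(scen, **overrides)
        name = type(spec).__name__
        return name, scen
    name = str(spec)
    return name, scenario(name, **overrides)


def run_benchmark(
    scenarios,
    methods=METHOD_ORDER,
    n_datasets: int = 10,
    alpha: float = 0.01,
    outliers: str = "both",
    seed: int = 0,
    n_testing_snps: int | None = None,
    n_inference_snps: int | None = None,
    outlier_config: OutlierInjectionConfig | None = None,
    gap_B: int = 100,
    collect_pvalues: bool = False,
    **method_options,
) -> BenchmarkTable:
    """Simulate, test and tabulate empirical rates over a scenario grid.

    Parameters
    ----------
    scenarios : iterable of scenario names or scenario objects
    methods : iterable of method names (see :data:`~robustps.assoc.METHODS`)
    outliers : {'none', 'only', 'both'}
        Whether cells are computed on clean data, contaminated data
        (5% injected subject outliers by default), or both.
    n_testing_snps, n_inference_snps : int, optional
        Scale overrides applied to every scenario; the full-scale study
        uses the scenario defaults.
    gap_B : int
        Reference-set count for the Gap statistic inside the clustering
        methods (reduced from the full-scale 1000 by default to keep
        desk-scale runs fast; the selected cluster count is insensitive
        to B, which only sharpens the simulation-error band).
    collect_pvalues : bool
        Also return raw pooled p-values per cell in ``table.attrs``.

    Per-dataset RNG seeds are derived as ``seed + dataset_index`` so
    that individual datasets can be regenerated in isolation.
    """
    if outliers not in ("none", "only", "both"):
        raise ValueError("outliers must be 'none', 'only' or 'both'")
    outlier_states = {"none": (False,), "only": (True,), "both": (False, True)}[outliers]
    cfg = outlier_config or OutlierInjectionConfig()
    overrides = {}
    if n_testing_snps is not None:
        overrides["n_testing_snps"] = n_testing_snps
    if n_inference_snps is not None:
        overrides["n_inference_snps"] = n_inference_snps

    rows = []
    failures = []
    pooled: dict[tuple, list] = {}
    for spec in scenarios:
        name, scen = _resolve_scenario(spec, overrides)
        for with_outliers in outlier_states:
            cell_p: dict[tuple, list] = {}
            for d in range(n_datasets):
                rng = np.random.default_rng(seed + d)
                dataset = simulate_scenario(scen, rng)
                if with_outliers:
                    dataset = inject_dataset_outliers(dataset, cfg, rng)
                for method in methods:
                    try:
                        results = run_method(
                            dataset, method, rng=rng, gap_B=gap_B, **method_options
                        )
                    except Exception as exc:  # keep the grid alive, record the cell
                        log.warning("cell (%s, %s, %s, ds %d) failed: %s", name, with_outliers, method, d, exc)
                        failures.append(
                            {
                                "scenario": name,
                                "outliers": with_outliers,
                                "method": method,
                                "dataset": d,
                                "error": repr(exc),
                            }
                        )
                        continue
                    roles = dataset.snp_role[np.isin(dataset.snp_role, ("random", "differentiated", "causal"))]
                    for res, role in zip(results, roles):
                        cell_p.setdefault((role, method), []).append(res.p_value)
            for (role, method), pvals in sorted(cell_p.items()):
                rows.append(
                    {
                        "scenario": name,
                        "outliers": with_outliers,
                        "snp_type": role,
                        "method": method,
                        "rate": empirical_rates(pvals, alpha=alpha),
                        "n_tests": len(pvals),
                    }
                )
                if collect_pvalues:
                    pooled[(name, with_outliers, role, method)] = np.asarray(pvals)
    table = pd.DataFrame(rows)
    if collect_pvalues:
        table.attrs["pvalues"] = pooled
    return BenchmarkTable(
        table=table,
        alpha=alpha,
        n_datasets=n_datasets,
        seed=seed,
        failures=failures,
    )
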