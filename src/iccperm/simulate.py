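"""Monte-Carlo engine for the type-I-error and power experiments.

For each (scenario, n) cell, ``n_reps`` datasets are generated; every
requested test is applied to each dataset (the naive and studentized
permutation tests share one set of B shuffles per dataset), and the cell
reports the rejection fraction at the nominal level, rejecting when
``p <= alpha``.  Every rate carries its Monte-Carlo standard error
``sqrt(r (1 - r) / n_reps)``.

Seeding: each cell gets a ``numpy.random.SeedSequence`` derived from the
master seed and a CRC-32 hash of the cell label (mode, scenario,
parameters, n); the cell then spawns one child sequence per replicate.
Cells are therefore independently reproducible, replicates are
independent streams, and restricting ``methods`` never changes the data a
cell sees.

Defaults mirror the reference study conditions: 10,000 replicates,
B = 1,000 permutations, alpha = 0.05, sizes {10, 25, 50, 100, 200}.
Reduced-rep runs are supported for desk-scale work; tolerance bands simply
widen as sqrt(1/n_reps).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import METHODS, _perm_core, f_test, fisher_z_test
from .errors import InvalidParameterError
from .scenarios import ScenarioSpec, generate, generate_power, resolve_scenario

__all__ = [
    "SimulationTable",
    "type1_study",
    "power_study",
    "summarize",
    "DEFAULT_SIZES",
]

DEFAULT_SIZES = (10, 25, 50, 100, 200)

#: long-format column order (the on-disk CSV schema)
LONG_COLUMNS = (
    "scenario", "param", "n", "method", "rejections", "n_reps", "rate",
    "mc_se", "B", "alpha", "seed",
)


@dataclass(frozen=True)
class SimulationTable:
    """Long-format rejection-rate grid with Monte-Carlo metadata.

    ``df`` has one row per (scenario, param, n, method) with columns
    :data:`LONG_COLUMNS`; rates live in ``rate`` with their MC standard
    error in ``mc_se``.
    """

    df: pd.DataFrame

    def wide(self) -> pd.DataFrame:
        """Per-scenario grid mirroring the published table layout.

        Rows are (scenario, param, n); one ``<method>`` rate column and one
        ``<method>_se`` column per method.
        """
        rate = self.df.pivot_table(
            index=["scenario", "param", "n"], columns="method", values="rate",
            sort=False,
        )
        se = self.df.pivot_table(
            index=["scenario", "param", "n"], columns="method", values="mc_se",
            sort=False,
        ).add_suffix("_se")
        order = [m for m in METHODS if m in rate.columns]
        out = pd.concat([rate[order], se[[m + "_se" for m in order]]], axis=1)
        return out.reset_index()


def _cell_seed_sequence(master_seed: int, label: str) -> np.random.SeedSequence:
    tag = zlib.crc32(label.encode("utf-8"))
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag])


def _run_cell(make_data, n, n_reps, B, alpha, methods, master_seed, label):
    """Rejection counts for one grid cell; all methods share each dataset."""
    ss = _cell_seed_sequence(master_seed, label)
    rejections = dict.fromkeys(methods, 0)
    need_perm = "permute" in methods or "stu_permute" in methods
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        ratings = make_data(n, rng)
        if "f_test" in methods:
            if f_test(ratings, alpha=alpha).p_value <= alpha:
                rejections["f_test"] += 1
        if "fisher_z" in methods:
            if fisher_z_test(ratings, alpha=alpha).p_value <= alpha:
                rejections["fisher_z"] += 1
        if need_perm:
            core = _perm_core(ratings.values[:, 0], ratings.values[:, 1], B, rng)
            if "permute" in methods and core.p_naive <= alpha:
                rejections["permute"] += 1
            if "stu_permute" in methods and core.p_stu is not None \
                    and core.p_stu <= alpha:
                rejections["stu_permute"] += 1
    return rejections


def _validate_grid(sizes, n_reps, B, alpha, methods):
    if not sizes:
        raise InvalidParameterError("empty list of sample sizes")
    if any(n < 3 for n in sizes):
        raise InvalidParameterError("every sample size must be >= 3")
    if n_reps < 1 or B < 1:
        raise InvalidParameterError("n_reps and B must be positive")
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError(f"alpha must lie in (0, 1), got {alpha}")
    bad = set(methods) - set(METHODS)
    if bad:
        raise InvalidParameterError(f"unknown methods {sorted(bad)}")


def _rows(scenario, param, n, rejections, n_reps, B, alpha, seed, methods):
    out = []
    if param is None:
        param = ""  # keeps parameterless scenarios in the wide pivot index
    for m in methods:
        r = rejections[m] / n_reps
        out.append({
            "scenario": scenario, "param": param, "n": n, "method": m,
            "rejections": rejections[m], "n_reps": n_reps, "rate": r,
            "mc_se": float(np.sqrt(r * (1.0 - r) / n_reps)),
            "B": B, "alpha": alpha, "seed": seed,
        })
    return out


def type1_study(
    scenarios,
    sizes=DEFAULT_SIZES,
    n_reps: int = 10_000,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    methods=METHODS,
    progress=None,
) -> SimulationTable:
    """Estimate null rejection rates over a scenario x size grid.

    Parameters
    ----------
    scenarios
        Iterable of scenario names (canonical or alias, e.g. ``"mvnx_9"``)
        or :class:`ScenarioSpec` objects; all must be null scenarios.
    sizes, n_reps, B, alpha, seed
        Grid and Monte-Carlo settings; see the module docstring.
    methods
        Subset of :data:`~iccperm.agreement.METHODS` to evaluate; the
        datasets drawn per cell do not depend on this choice.
    progress
        Optional callable invoked as ``progress(label, n)`` after each cell
        (used by the CLI for timing logs).
    """
    specs = [resolve_scenario(s) for s in scenarios]
    if not specs:
        raise InvalidParameterError("empty list of scenarios")
    sizes = [int(n) for n in sizes]
    methods = tuple(methods)
    _validate_grid(sizes, n_reps, B, alpha, methods)

    rows = []
    for spec in specs:
        param = spec.params.get("rho")
        for n in sizes:
            label = f"type1|{spec.label}|{n}"
            sized = spec.with_n(n)
            rej = _run_cell(
                lambda nn, rng, s=sized: generate(s, rng),
                n, n_reps, B, alpha, methods, seed, label,
            )
            rows.extend(_rows(spec.label, param, n, rej, n_reps, B, alpha,
                              seed, methods))
            if progress is not None:
                progress(label, n)
    return SimulationTable(pd.DataFrame(rows, columns=list(LONG_COLUMNS)))


def power_study(
    rhos,
    sizes=DEFAULT_SIZES,
    n_reps: int = 10_000,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    methods=METHODS,
    progress=None,
) -> SimulationTable:
    """Estimate power against bivariate-normal alternatives with ICC = rho.

    Same mechanics as :func:`type1_study` over :func:`generate_power`
    draws; each ``rho`` must lie in (0, 1).
    """
    rhos = [float(r) for r in rhos]
    if not rhos:
        raise InvalidParameterError("empty list of rho values")
    for r in rhos:
        if not 0.0 < r < 1.0:
            raise InvalidParameterError(f"power rho must lie in (0, 1), got {r}")
    sizes = [int(n) for n in sizes]
    methods = tuple(methods)
    _validate_grid(sizes, n_reps, B, alpha, methods)

    rows = []
    for rho in rhos:
        for n in sizes:
            label = f"power|bvn(rho={rho!r})|{n}"
            rej = _run_cell(
                lambda nn, rng, r=rho: generate_power(r, nn, rng),
                n, n_reps, B, alpha, methods, seed, label,
            )
            rows.extend(_rows("bvn", rho, n, rej, n_reps, B, alpha, seed,
                              methods))
            if progress is not None:
                progress(label, n)
    return SimulationTable(pd.DataFrame(rows, columns=list(LONG_COLUMNS)))


def summarize(table: SimulationTable, out_dir=None, prefix: str = "simulation"):
    """Long-format and wide per-scenario views of a simulation table.

    Returns ``(long_df, wide_df)``.  If ``out_dir`` is given, writes
    ``<prefix>_long.csv`` and ``<prefix>_wide.csv`` there; re-reading the
    long CSV reproduces the rejection rates bit-exactly (rates are ratios
    of the integer columns also stored).
    """
    if table.df.empty:
        raise InvalidParameterError("cannot summarize an empty table")
    long_df = table.df.copy()
    wide_df = table.wide()
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        long_df.to_csv(os.path.join(out_dir, f"{prefix}_long.csv"), index=False)
        wide_df.to_csv(os.path.join(out_dir, f"{prefix}_wide.csv"), index=False)
    return long_df, wide_df
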