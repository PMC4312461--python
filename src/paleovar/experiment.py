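"""Factorial grid orchestration and regression summaries.

Runs the full treatment grid — GC content x divergence x read length x
damage level x coverage depth, with replicate genome pairs — producing one
``EvalSummary`` row per read pool, replicate-averaged per cell, and fits
ordinary least-squares regressions of the pool metrics on the treatment
variables (damage coded 1/2/3; depth either linear or log-transformed),
separately per divergence level.

Within one (pair, read length, damage) series the deepest accepted pool is
mapped once and shallower depths are nested prefix subsets of it; read
selection order is random, so subsampling before or after mapping is
statistically equivalent and each read is aligned exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import align_call, damage_sim, read_sim
from .damage_sim import DamageConfig
from .evaluate import EvalSummary, summarize
from .genome_sim import GenomeSimConfig, ReferenceSamplePair, simulate_pair
from .read_sim import ErrorModel, TrimDistribution
from .rng import child_seed, substream

__all__ = [
    "GridConfig",
    "RegressionResult",
    "run_grid",
    "run_pool_series",
    "average_replicates",
    "regress",
    "compare_slopes",
    "DAMAGE_CODE",
]

DAMAGE_CODE = {"none": 1, "low": 2, "high": 3}


@dataclass
class GridConfig:
    """The factorial design and pipeline settings for one grid run.

    Defaults are a reduced-scale design (shorter genomes, one replicate);
    the full-scale study uses ``length_bp=10_001_000`` and ``replicates=3``.
    """

    gc_levels: tuple = (0.35, 0.50, 0.65)
    divergences: tuple = ("low", "high")
    read_len_means: tuple = (40, 60, 80)
    damage_levels: tuple = ("none", "low", "high")
    depths: tuple = (0.1, 0.5, 1, 2, 4, 8, 16)
    replicates: int = 1
    length_bp: int = 1_000_000
    raw_read_len: int = 100
    raw_coverage: float | None = None  # None: derived from the deepest pool
    phred_quality: int = 35
    k: int = 13
    max_mismatch_frac: float = 0.05
    band: int = 6
    min_qual: float = 20.0
    min_depth: int = 1
    max_depth: int = 30
    edge_margin: int = 500
    indel_window: int = 3
    indel_exclusion: int = 5
    master_seed: int = 0

    def needed_raw_coverage(self) -> float:
        """Per-chromosome raw coverage for the deepest, least-accepting cell.

        Worst case: shortest trim mean (largest trim loss) and the
        high-damage acceptance rate (~0.195 of candidates); a 1.35x safety
        factor covers sampling fluctuations and mean-length wobble.
        """
        if self.raw_coverage is not None:
            return self.raw_coverage
        trim_ratio = min(self.read_len_means) / self.raw_read_len
        worst_accept = 0.18
        return 1.35 * max(self.depths) / (2 * trim_ratio * worst_accept)


@dataclass
class RegressionResult:
    dependent: str
    form: str
    params: dict  # name -> slope
    bse: dict
    pvalues: dict
    r_squared: float
    n_obs: int


def _pair_for(cfg: GridConfig, gc: float, divergence: str, rep: int) -> ReferenceSamplePair:
    seed = child_seed(cfg.master_seed, f"pair:{gc}:{divergence}:{rep}")
    return simulate_pair(
        GenomeSimConfig(
            length_bp=cfg.length_bp,
            gc_content=gc,
            divergence_level=divergence,
            seed=seed,
        )
    )


def run_pool_series(
    pair: ReferenceSamplePair,
    index: align_call.ReferenceIndex,
    raw_reads: list,
    read_len_mean: int,
    damage_level: str,
    depths: tuple,
    cfg: GridConfig,
    tag: str,
) -> dict[float, EvalSummary]:
    """Evaluate one (pair, read length, damage) series across depths.

    Returns a mapping depth -> EvalSummary. Shallower depths are nested
    prefixes of the deepest accepted pool, whose reads are mapped once.
    """
    L = len(pair.reference)
    chroms = [pair.chromosome1, pair.chromosome2]
    trim_rng = substream(cfg.master_seed, f"trim:{tag}:{read_len_mean}")
    trimmed = read_sim.trim_pool(
        raw_reads, TrimDistribution(mean_len=read_len_mean), trim_rng
    )
    dmg_cfg = DamageConfig.preset(damage_level)
    dmg_rng = substream(cfg.master_seed, f"damage:{tag}:{read_len_mean}:{damage_level}")
    accepted = damage_sim.build_damaged_pool(
        trimmed, chroms, dmg_cfg, dmg_rng, max_bases=max(depths) * L * 1.01 + 200
    )
    mapped_all = [
        align_call.map_read(r, index, cfg.max_mismatch_frac, cfg.band) for r in accepted
    ]
    out: dict[float, EvalSummary] = {}
    lengths = np.array([len(r) for r in accepted])
    cum = np.cumsum(lengths)
    for depth in depths:
        target = depth * L
        if cum.size == 0 or cum[-1] < target:
            raise ValueError(
                f"accepted pool reaches only {cum[-1] / L if cum.size else 0:.2f}x, "
                f"need {depth}x; increase raw_coverage"
            )
        n_take = int(np.searchsorted(cum, target)) + 1
        mapped = [m for m in mapped_all[:n_take] if m is not None]
        calls = align_call.pileup_and_call(
            mapped, pair.reference, phred=cfg.phred_quality
        )
        calls = align_call.filter_calls(calls, cfg.min_depth, cfg.max_depth, cfg.min_qual)
        out[depth] = summarize(
            pair,
            n_take,
            mapped,
            calls,
            window=cfg.indel_window,
            indel_exclusion=cfg.indel_exclusion,
            edge_margin=cfg.edge_margin,
        )
    return out


def run_grid(cfg: GridConfig, progress: bool = False) -> pd.DataFrame:
    """Run the factorial grid; one row per read pool (replicate-resolved).

    A failing cell is recorded with ``failed=True`` and NaN metrics; the
    run continues.
    """
    rows = []
    raw_cov = cfg.needed_raw_coverage()
    error_model = ErrorModel(cfg.phred_quality)
    for divergence in cfg.divergences:
        for gc in cfg.gc_levels:
            for rep in range(cfg.replicates):
                tag = f"{gc}:{divergence}:{rep}"
                pair = _pair_for(cfg, gc, divergence, rep)
                index = align_call.build_index(pair.reference, cfg.k)
                read_rng = substream(cfg.master_seed, f"reads:{tag}")
                raw_reads = read_sim.generate_raw_reads(
                    [pair.chromosome1, pair.chromosome2],
                    raw_read_len=cfg.raw_read_len,
                    raw_coverage=raw_cov,
                    error_model=error_model,
                    rng=read_rng,
                )
                for read_len in cfg.read_len_means:
                    for damage in cfg.damage_levels:
                        base = {
                            "gc": gc * 100,
                            "divergence": divergence,
                            "read_len": read_len,
                            "damage": damage,
                            "damage_code": DAMAGE_CODE[damage],
                            "replicate": rep,
                        }
                        try:
                            series = run_pool_series(
                                pair, index, raw_reads, read_len, damage,
                                cfg.depths, cfg, tag,
                            )
                            for depth, summ in series.items():
                                rows.append(
                                    {**base, "depth": depth, "failed": False,
                                     **summ.as_dict()}
                                )
                        except Exception as exc:  # noqa: BLE001 - cell flagged
                            for depth in cfg.depths:
                                rows.append(
                                    {**base, "depth": depth, "failed": True,
                                     "error": str(exc)}
                                )
                        if progress:
                            print(f"[grid] {tag} len={read_len} damage={damage} done")
    return pd.DataFrame(rows)


_METRICS = [
    "pct_reads_mapped",
    "mean_mapped_read_len",
    "pct_unique_5prime_starts",
    "snp_accuracy",
    "indel_accuracy",
    "snp_completeness",
    "indel_completeness",
    "snp_homhet_ratio_of_ratios",
    "indel_homhet_ratio_of_ratios",
]


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average replicate pools per grid cell (mean of ratios), keeping sd."""
    keys = ["gc", "divergence", "read_len", "damage", "damage_code", "depth"]
    metrics = [m for m in _METRICS if m in table.columns]
    grouped = table.groupby(keys, sort=True)[metrics]
    mean = grouped.mean().reset_index()
    sd = grouped.std().reset_index()[metrics].add_suffix("_sd")
    return pd.concat([mean, sd], axis=1)


def regress(
    table: pd.DataFrame,
    dependent: str,
    independents: tuple = ("gc", "read_len", "damage_code", "depth"),
    form: str = "linear",
) -> RegressionResult:
    """OLS of a pool metric on the treatment variables (with intercept).

    ``form="log-depth"`` replaces depth by log(depth). Rows with missing
    dependent values (e.g. zero-call pools) are dropped listwise.
    """
    if form not in ("linear", "log-depth"):
        raise ValueError("form must be 'linear' or 'log-depth'")
    cols = table[list(independents) + [dependent]].dropna()
    if len(cols) < len(independents) + 2:
        raise ValueError("too few rows for regression")
    X = cols[list(independents)].astype(float).copy()
    if form == "log-depth" and "depth" in X:
        X["depth"] = np.log(X["depth"])
        X = X.rename(columns={"depth": "log_depth"})
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.values]))
    if rank < X.shape[1] + 1:
        const = [c for c in X.columns if X[c].nunique() <= 1]
        raise ValueError(f"rank-deficient design; collinear columns: {const or X.columns.tolist()}")
    fit = sm.OLS(cols[dependent].astype(float), sm.add_constant(X)).fit()
    names = [n for n in fit.params.index if n != "const"]
    return RegressionResult(
        dependent=dependent,
        form=form,
        params={n: float(fit.params[n]) for n in names},
        bse={n: float(fit.bse[n]) for n in names},
        pvalues={n: float(fit.pvalues[n]) for n in names},
        r_squared=float(fit.rsquared),
        n_obs=int(fit.nobs),
    )


def compare_slopes(
    table: pd.DataFrame,
    dependent: str,
    x: str = "depth",
    group: str = "divergence",
) -> dict:
    """ANCOVA-style slope comparison between two groups.

    Fits ``dependent ~ x * group`` and reports the interaction (slope
    difference) estimate and its p-value.
    """
    cols = table[[x, group, dependent]].dropna()
    levels = sorted(cols[group].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two {group} groups, got {levels}")
    g = (cols[group] == levels[1]).astype(float)
    X = pd.DataFrame(
        {x: cols[x].astype(float), "group": g, "interaction": cols[x].astype(float) * g}
    )
    fit = sm.OLS(cols[dependent].astype(float), sm.add_constant(X)).fit()
    return {
        "groups": levels,
        "slope_difference": float(fit.params["interaction"]),
        "p_value": float(fit.pvalues["interaction"]),
    }
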