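"""Study runner and evaluation: ROC comparison of statistics and
bias/variability of pi1 estimates across the scenario factorial."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import estimators as est
from .perm_null import PooledNull, pooled_null_pvalues, permutation_labels
from .simulation import ScenarioConfig, simulate_dataset, synth_parameter_table
from .stats_core import (
    FAMILY_PERCENTILE,
    STATISTIC_FAMILIES,
    TestStatisticVector,
    delta_from_percentile,
    group_summaries,
    rescale_statistics,
    s_statistics,
    t_statistics,
)

__all__ = ["RocCurve", "roc_curve", "run_study", "summarize_bias"]

RESULT_COLUMNS = [
    "sim_type", "n1", "n2", "pi1", "G", "rescale", "input_spec",
    "replicate", "family", "estimator", "pi1_hat", "note",
]


@dataclass
class RocCurve:
    """Empirical ROC of ranking genes by |statistic| against the DE truth."""

    thresholds: np.ndarray
    fpf: np.ndarray
    tpf: np.ndarray
    auc: float


def roc_curve(stats: TestStatisticVector | np.ndarray, truth: np.ndarray) -> RocCurve:
    """Tie-grouped empirical ROC; all genes sharing one |statistic| advance
    together.  AUC is the trapezoidal integral of TPF over FPF."""
    vals = stats.values if isinstance(stats, TestStatisticVector) else np.asarray(stats, float)
    truth = np.asarray(truth, bool)
    if len(vals) != len(truth):
        raise ValueError("statistic and truth vectors must have equal length")
    finite = np.isfinite(vals)
    if not finite.all():
        warnings.warn(
            f"{int((~finite).sum())} non-finite statistic(s) excluded from ROC",
            RuntimeWarning,
            stacklevel=2,
        )
        vals, truth = vals[finite], truth[finite]
    if truth.all() or not truth.any():
        raise ValueError("need at least one DE and one non-DE gene for a ROC curve")
    fpf, tpf, thr = _sk_roc_curve(truth, np.abs(vals), drop_intermediate=False)
    auc = float(np.trapezoid(tpf, fpf))
    return RocCurve(thresholds=thr, fpf=fpf, tpf=tpf, auc=auc)


def _all_family_statistics(data, families=STATISTIC_FAMILIES):
    """Observed t- and s-statistics, sharing one pass over the data."""
    summ = group_summaries(data)
    t = t_statistics(summ, data.n1, data.n2)
    out = {"t": t}
    for fam in families:
        if fam == "t":
            continue
        delta = delta_from_percentile(t.denominators, FAMILY_PERCENTILE[fam])
        out[fam] = s_statistics(summ, data.n1, data.n2, delta, family=fam)
    return out


def _pooled_nulls_all_families(data, labels, families=STATISTIC_FAMILIES):
    """Pooled permutation nulls for every family from one permutation pass.

    Per permutation the group means/variances are computed once; each
    family's statistic (with its delta recomputed from that permutation's
    t-denominators) is derived from them.
    """
    chunks: dict[str, list[np.ndarray]] = {f: [] for f in families}
    for mask in labels:
        x1 = data.values[:, mask]
        x2 = data.values[:, ~mask]
        diff = x1.mean(axis=1) - x2.mean(axis=1)
        denom = np.sqrt(
            x1.var(axis=1, ddof=1) / data.n1 + x2.var(axis=1, ddof=1) / data.n2
        )
        for fam in families:
            pct = FAMILY_PERCENTILE[fam]
            delta = 0.0 if pct is None else delta_from_percentile(denom, pct)
            full = delta + denom
            with np.errstate(divide="ignore", invalid="ignore"):
                stat = diff / full
            chunks[fam].append(np.where(full == 0, np.nan, stat))
    nulls = {}
    for fam in families:
        pooled = np.concatenate(chunks[fam])
        finite = np.isfinite(pooled)
        nulls[fam] = PooledNull(
            null_values=pooled[finite],
            B=len(labels),
            statistic_family=fam,
            n_dropped=int((~finite).sum()),
        )
    return nulls


def _estimate_all(config, stats_by_family, nulls, df):
    """One row per (family, estimator); estimator failures become NaN rows."""
    rows = []
    base = dict(
        sim_type=config.sim_type, n1=config.n1, n2=config.n2, pi1=config.pi1,
        G=config.G, rescale=config.rescale, input_spec=config.input_spec,
        replicate=config.replicate,
    )
    t_stats = stats_by_family["t"]
    for fam, stats in stats_by_family.items():
        if fam == "t":
            en_input = stats
        else:
            en_input = rescale_statistics(stats, t_stats, measure=config.rescale)
        jobs = {
            "empirical_null": lambda s=en_input: est.estimate_pi0_empirical_null(
                s, input_family=config.input_spec,
                df=df if config.input_spec == "t" else None,
            )[0],
        }
        try:
            pvals = pooled_null_pvalues(stats, nulls[fam])
        except Exception as exc:  # pragma: no cover - defensive
            pvals = None
            pv_err = str(exc)
        if pvals is not None:
            jobs["storey"] = lambda p=pvals: est.estimate_pi0_storey(p)
            jobs["convest"] = lambda p=pvals: est.estimate_pi0_convest(p)[0]
        for name, job in jobs.items():
            row = dict(base, family=fam, estimator=name)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    row["pi1_hat"] = job().pi1
                    row["note"] = ""
            except Exception as exc:
                row["pi1_hat"] = np.nan
                row["note"] = f"failed: {exc}"
            rows.append(row)
        if pvals is None:
            for name in ("storey", "convest"):
                rows.append(
                    dict(base, family=fam, estimator=name, pi1_hat=np.nan,
                         note=f"failed: {pv_err}")
                )
    return rows


def run_study(
    grid: list[ScenarioConfig],
    replicates: int = 20,
    B: int = 100,
    master_seed: int = 0,
    families=STATISTIC_FAMILIES,
    estimator_subset: set[str] | None = None,
) -> pd.DataFrame:
    """Run the full pipeline over scenarios x replicates.

    For each cell: simulate a dataset, compute the t- and s-statistics,
    rescale per the scenario, build the pooled permutation null, and
    estimate pi1 with the empirical-null method (on statistics), the
    smoother method and the convex-density NPMLE (both on pooled-null
    P-values).  Individual estimator failures are recorded as NaN rows with
    a reason, never aborting the grid.
    """
    all_rows = []
    for config in grid:
        for rep in range(replicates):
            cfg = ScenarioConfig(
                sim_type=config.sim_type, n1=config.n1, n2=config.n2,
                pi1=config.pi1, G=config.G, rescale=config.rescale,
                input_spec=config.input_spec, replicate=rep,
            )
            ss = cfg.derived_seed(master_seed)
            param_seed, data_seed, perm_seed = ss.spawn(3)
            params = synth_parameter_table(cfg.G, cfg.pi1, seed=param_seed)
            dataset = simulate_dataset(params, cfg, seed=data_seed)
            stats_by_family = _all_family_statistics(dataset.data, families)
            n_perm = min(B, _max_permutations(cfg.n1, cfg.n2))
            labels = permutation_labels(
                cfg.n1, cfg.n2, n_perm,
                seed=np.random.default_rng(perm_seed).integers(2**31),
            )
            nulls = _pooled_nulls_all_families(dataset.data, labels, families)
            df = cfg.n1 + cfg.n2 - 2
            rows = _estimate_all(cfg, stats_by_family, nulls, df)
            if estimator_subset is not None:
                rows = [r for r in rows if r["estimator"] in estimator_subset]
            all_rows.extend(rows)
    return pd.DataFrame(all_rows, columns=RESULT_COLUMNS)


def _max_permutations(n1: int, n2: int) -> int:
    from math import comb

    return comb(n1 + n2, n1) - 1


def summarize_bias(results: pd.DataFrame) -> pd.DataFrame:
    """Per (scenario, family, estimator) cell: median pi1-hat, IQR and bias.

    Bias = median(pi1-hat) - true pi1; a negative sign labels the cell
    conservative, positive anticonservative.  Cells with fewer than 2
    finite replicates are omitted with a warning.
    """
    keys = ["sim_type", "n1", "n2", "pi1", "G", "rescale", "input_spec",
            "family", "estimator"]
    out = []
    for key, grp in results.groupby(keys, sort=False):
        vals = grp["pi1_hat"].dropna().to_numpy()
        if vals.size < 2:
            warnings.warn(
                f"cell {key} has {vals.size} finite replicate(s); omitted",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        med = float(np.median(vals))
        q75, q25 = np.percentile(vals, [75, 25])
        rec = dict(zip(keys, key))
        rec.update(
            n_replicates=int(vals.size),
            median_pi1_hat=med,
            iqr_pi1_hat=float(q75 - q25),
            bias=med - rec["pi1"],
        )
        rec["direction"] = "conservative" if rec["bias"] < 0 else (
            "anticonservative" if rec["bias"] > 0 else "unbiased"
        )
        out.append(rec)
    return pd.DataFrame(out)
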