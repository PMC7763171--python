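"""Stability validation of a differential-signal signature.

Two complementary checks:

* **bootstrap_validate** — draw B datasets by resampling samples with
  replacement, stratified within each group so the original group-size
  ratio is conserved exactly, re-run SAM on each, and count per signal how
  often it comes out significant with the same effect direction as in the
  original analysis (Efron-style occurrence-frequency validation).
* **regress_adjusted** — covariate-adjusted group difference from the linear
  model  abundance = β0 + β·group + γ·covariate, with a robust standard
  error for β from a non-parametric case-resampling bootstrap; the 95% CI is
  β ± 1.96·SE_boot and the p-value uses the normal approximation. Age and
  gender are adjusted in separate models by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .differential import SamConfig, sam_two_class
from .preprocess_align import AlignedTable

__all__ = ["BootstrapConfig", "RegressionResult", "bootstrap_validate", "regress_adjusted"]


@dataclass
class BootstrapConfig:
    n_datasets: int = 100
    with_replacement: bool = True
    preserve_group_ratio: bool = True
    significance_rule: str = "p_lt_0.05"  # or "q_le_threshold"
    seed: int = 0
    max_redraws: int = 100

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if self.significance_rule not in ("p_lt_0.05", "q_le_threshold"):
            raise ValueError(f"unknown significance_rule {self.significance_rule!r}")
        if not self.with_replacement:
            raise ValueError("only resampling with replacement is supported")


@dataclass
class RegressionResult:
    signal: float
    group_a: str
    group_b: str
    covariate: str
    mean_difference: float
    ci_lower: float
    ci_upper: float
    p_value: float
    se_boot: float
    n_boot: int

    def as_dict(self) -> dict:
        return {
            "signal": self.signal, "comparison": f"{self.group_a}_vs_{self.group_b}",
            "covariate": self.covariate, "mean_difference": self.mean_difference,
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "p_value": self.p_value,
        }


def _resample_columns(groups: pd.Series, rng: np.random.Generator,
                      max_redraws: int) -> list[str]:
    """Stratified with-replacement resample conserving each group's size.

    A draw where some group collapses onto a single unique sample is redrawn
    (it would give that group zero scatter across the board).
    """
    cols: list[str] = []
    for g in groups.unique():
        ids = groups.index[groups == g].to_numpy()
        for _ in range(max_redraws):
            draw = rng.choice(ids, size=ids.size, replace=True)
            if np.unique(draw).size > 1 or ids.size == 1:
                break
        cols.extend(draw.tolist())
    return cols


def bootstrap_validate(table: AlignedTable,
                       comparisons: dict[str, tuple[str, str]],
                       sam_cfg: SamConfig | None = None,
                       boot_cfg: BootstrapConfig | None = None,
                       signals: list[float] | None = None) -> pd.DataFrame:
    """Occurrence-frequency validation of candidate signals.

    For each comparison, SAM runs once on the original table to fix the
    candidate signals (those at or below the q threshold, unless ``signals``
    is given) and their effect directions; then on each of ``n_datasets``
    stratified bootstrap resamples. A dataset counts as an occurrence for a
    signal when the significance rule holds *and* the effect direction
    matches the original.

    Returns a tidy report: comparison, signal, original q-value, occurrences,
    n_datasets, direction-consistency flag.
    """
    sam_cfg = sam_cfg or SamConfig()
    boot_cfg = boot_cfg or BootstrapConfig()
    rng = np.random.default_rng(boot_cfg.seed)
    groups = table.groups()
    rows = []
    for name, (ga, gb) in comparisons.items():
        original = sam_two_class(table, ga, gb, sam_cfg)
        if signals is None:
            cand = original.significant(sam_cfg.q_threshold).index.tolist()
        else:
            cand = [s for s in signals if s in original.stats.index]
        if not cand:
            continue
        orig_sign = np.sign(original.stats.loc[cand, "numerator"])
        occurrences = pd.Series(0, index=cand, dtype=int)
        pair_groups = groups[groups.isin([ga, gb])]
        for b in range(boot_cfg.n_datasets):
            cols = _resample_columns(pair_groups, rng, boot_cfg.max_redraws)
            boot_samples = table.samples.loc[cols].copy()
            boot_ids = [f"b{k}" for k in range(len(cols))]
            boot_samples.index = boot_ids
            boot_ab = table.abundance[cols].copy()
            boot_ab.columns = boot_ids
            boot_table = AlignedTable(boot_ab, boot_samples, provenance=dict(table.provenance))
            boot_cfg_seed = replace(sam_cfg, seed=int(rng.integers(2 ** 31)))
            res = sam_two_class(boot_table, ga, gb, boot_cfg_seed)
            if boot_cfg.significance_rule == "p_lt_0.05":
                hit = res.stats.loc[cand, "p_value"] < 0.05
            else:
                hit = res.stats.loc[cand, "q_value"] <= sam_cfg.q_threshold
            same_dir = np.sign(res.stats.loc[cand, "numerator"]) == orig_sign
            occurrences += (hit & same_dir).astype(int)
        for sig in cand:
            rows.append({
                "comparison": name,
                "signal": sig,
                "q_value_original": original.stats.loc[sig, "q_value"],
                "occurrences": int(occurrences[sig]),
                "n_datasets": boot_cfg.n_datasets,
                "direction_consistent": True,  # opposite-direction hits are not counted
            })
    return pd.DataFrame(rows, columns=["comparison", "signal", "q_value_original",
                                       "occurrences", "n_datasets", "direction_consistent"])


def _encode_covariate(values: pd.Series, covariate: str) -> np.ndarray:
    if covariate == "gender":
        return (values.astype(str).str.upper().str.startswith("M")).to_numpy(dtype=float)
    return values.to_numpy(dtype=float)


def regress_adjusted(table: AlignedTable, signal: float,
                     group_pair: tuple[str, str], covariate: str,
                     n_boot: int = 1000, seed: int = 0) -> RegressionResult:
    """Covariate-adjusted mean abundance difference with bootstrap SE.

    β is the difference in mean abundance between cases (second group of the
    pair) and controls after adjusting for the covariate. Its standard error
    comes from ``n_boot`` case-resampling bootstrap refits; the 95% CI is
    β ± 1.96·SE and the p-value is two-sided normal. A constant covariate is
    dropped with a warning, reducing β to the raw difference of means.
    """
    from scipy import stats as sps

    ga, gb = group_pair
    groups = table.groups()
    cols = groups.index[groups.isin([ga, gb])]
    if signal not in table.abundance.index:
        raise KeyError(f"signal {signal} not in table")
    if covariate not in table.samples.columns:
        raise KeyError(f"covariate {covariate!r} not in sample annotations")
    y = table.abundance.loc[signal, cols].to_numpy(dtype=float)
    g = (groups[cols] == gb).to_numpy(dtype=float)
    z = _encode_covariate(table.samples.loc[cols, covariate], covariate)

    if np.ptp(z) == 0:
        import warnings
        warnings.warn(f"covariate {covariate!r} is constant; estimate is the "
                      "unadjusted difference of means", stacklevel=2)
        design = np.column_stack([np.ones_like(g), g])
    else:
        design = np.column_stack([np.ones_like(g), g, z])

    fit = sm.OLS(y, design).fit()
    beta = float(fit.params[1])

    rng = np.random.default_rng(seed)
    n = y.size
    betas = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = design[idx], y[idx]
        if np.ptp(xb[:, 1]) == 0:  # resample lost one group; redraw
            idx = rng.integers(0, n, size=n)
            xb, yb = design[idx], y[idx]
        coef, *_ = np.linalg.lstsq(xb, yb, rcond=None)
        betas[b] = coef[1]
    se = float(betas.std(ddof=1))
    ci_lo, ci_hi = beta - 1.96 * se, beta + 1.96 * se
    p = float(2 * sps.norm.sf(abs(beta) / se)) if se > 0 else 0.0
    return RegressionResult(signal=float(signal), group_a=ga, group_b=gb,
                            covariate=covariate, mean_difference=beta,
                            ci_lower=ci_lo, ci_upper=ci_hi, p_value=p,
                            se_boot=se, n_boot=n_boot)
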