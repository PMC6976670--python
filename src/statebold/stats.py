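"""EEG-informed trial statistics: correlation, weak/strong category analysis,
permutation nulls, drift checks and the specificity battery.

Two complementary trial-level analyses link pre-event oscillatory power to
single-trial evoked BOLD amplitude within each region:

* the Pearson correlation of power and amplitude across trials, and
* a category contrast between the ``bin_size`` weakest-power and
  ``bin_size`` strongest-power trials.

Significance of both comes from the same permutation engine: the evoked
amplitude estimates are randomly re-labelled against the fixed power
values, giving a null distribution of the statistic. Alpha-band tests are
one-tailed toward negative effects (alpha power is expected to suppress
evoked responses); all other tests are two-tailed. Effect size for the
category contrast is Cohen's d for dependent samples on rank-paired
differences.
"""
from __future__ import annotations

import math
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "PermutationConfig",
    "PermutationResult",
    "CategoryResult",
    "StateDependenceResult",
    "correlate_power_bold",
    "permutation_test",
    "category_analysis",
    "drift_check",
    "specificity_battery",
]


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the permutation engine.

    ``tails`` maps band name to tail policy: ``one_neg`` (one-tailed
    toward negative statistics) or ``two``.
    """

    n_perm: int = 20000
    bin_size: int = 40
    seed: int = 0
    tails: dict = field(default_factory=lambda: {"alpha": "one_neg", "beta": "two"})

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")

    def tail_for(self, band: str) -> str:
        return self.tails.get(band, "two")


@dataclass
class PermutationResult:
    observed: float
    p: float
    n_perm: int
    tail: str
    exhaustive: bool = False


@dataclass
class CategoryResult:
    weak_mean: float
    strong_mean: float
    diff: float  # strong - weak
    p: float
    d: float  # dependent-samples Cohen's d on rank-paired differences
    n_perm: int
    tail: str


def correlate_power_bold(power: np.ndarray, betas: np.ndarray) -> float:
    """Pearson correlation of pre-event power and evoked amplitude.

    A constant input yields rho = 0 with a warning rather than NaN.
    """
    power = np.asarray(power, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if power.shape != betas.shape or power.ndim != 1:
        raise ValueError("power and betas must be equal-length vectors")
    if len(power) < 3:
        raise ValueError("need at least 3 trials")
    if power.std() == 0 or betas.std() == 0:
        warnings.warn("constant input; correlation defined as 0")
        return 0.0
    return float(np.corrcoef(power, betas)[0, 1])


def _category_indices(power: np.ndarray, bin_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Stable-sorted weak / strong trial index sets (ties broken by order)."""
    order = np.argsort(power, kind="stable")
    return order[:bin_size], order[-bin_size:]


def _category_diff(betas: np.ndarray, weak: np.ndarray, strong: np.ndarray) -> float:
    return float(betas[strong].mean() - betas[weak].mean())


def _tail_p(null: np.ndarray, observed: float, tail: str) -> float:
    """Smoothed permutation p: (1 + #{null as or more extreme}) / (B + 1)."""
    if tail == "one_neg":
        extreme = np.sum(null <= observed)
    elif tail == "two":
        extreme = np.sum(np.abs(null) >= abs(observed))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float((1 + extreme) / (len(null) + 1))


def permutation_test(
    power: np.ndarray,
    betas: np.ndarray,
    statistic: str = "corr",
    cfg: PermutationConfig | None = None,
    tail: str | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Permutation p-value for the power-amplitude association.

    The amplitude vector is permuted against the fixed power vector
    ``cfg.n_perm`` times; when n! does not exceed ``cfg.n_perm`` all n!
    permutations are enumerated instead (exact p, same smoothing
    convention). ``statistic`` is ``corr`` or ``category_diff``.
    """
    cfg = cfg or PermutationConfig()
    if tail is None:
        tail = cfg.tail_for("alpha")
    power = np.asarray(power, dtype=float)
    betas = np.asarray(betas, dtype=float)
    n = len(power)
    if len(betas) != n:
        raise ValueError("power and betas must have equal length")

    if statistic == "corr":
        if power.std() == 0 or betas.std() == 0:
            warnings.warn("constant input; permutation test degenerate")
            return PermutationResult(observed=0.0, p=1.0, n_perm=cfg.n_perm, tail=tail)
        zp = (power - power.mean()) / power.std()

        def stat(b: np.ndarray) -> np.ndarray:
            zb = (b - b.mean(axis=-1, keepdims=True)) / b.std(axis=-1, keepdims=True)
            return (zb @ zp) / n

    elif statistic == "category_diff":
        if 2 * cfg.bin_size > n:
            raise ValueError(
                f"need at least {2 * cfg.bin_size} trials for bin_size={cfg.bin_size}, got {n}"
            )
        weak, strong = _category_indices(power, cfg.bin_size)

        def stat(b: np.ndarray) -> np.ndarray:
            b2 = np.atleast_2d(b)
            out = b2[:, strong].mean(axis=1) - b2[:, weak].mean(axis=1)
            return out if b.ndim > 1 else out[0]

    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    observed = float(stat(betas))

    exhaustive = math.factorial(n) <= cfg.n_perm
    if exhaustive:
        perms = np.array(list(itertools.permutations(betas)))
        null = np.asarray(stat(perms), dtype=float)
    else:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        perms = rng.permuted(np.tile(betas, (cfg.n_perm, 1)), axis=1)
        null = np.asarray(stat(perms), dtype=float)
    p = _tail_p(null, observed, tail)
    return PermutationResult(
        observed=observed, p=p, n_perm=len(null), tail=tail, exhaustive=exhaustive
    )


def category_analysis(
    power: np.ndarray,
    betas: np.ndarray,
    cfg: PermutationConfig | None = None,
    tail: str | None = None,
    rng: np.random.Generator | None = None,
) -> CategoryResult:
    """Weak-power vs strong-power category contrast of evoked amplitudes.

    Trials are sorted by power (stable sort; ties broken by trial order);
    the lowest and highest ``bin_size`` form the weak and strong
    categories. The mean difference (strong - weak) is tested with the
    permutation engine, and Cohen's d for dependent samples is computed on
    rank-paired differences: the i-th lowest-power trial of the weak bin is
    paired with the i-th lowest-power trial of the strong bin, and the mean
    of those differences is divided by their standard deviation (d = 0 by
    convention when the differences are constant).
    """
    cfg = cfg or PermutationConfig()
    if tail is None:
        tail = cfg.tail_for("alpha")
    power = np.asarray(power, dtype=float)
    betas = np.asarray(betas, dtype=float)
    n = len(power)
    if 2 * cfg.bin_size > n:
        raise ValueError(
            f"category analysis needs >= {2 * cfg.bin_size} retained trials, got {n}"
        )
    weak, strong = _category_indices(power, cfg.bin_size)
    weak_mean = float(betas[weak].mean())
    strong_mean = float(betas[strong].mean())
    perm = permutation_test(power, betas, statistic="category_diff", cfg=cfg, tail=tail, rng=rng)
    # rank pairing: both bins ascend in power within themselves already
    diffs = betas[strong] - betas[weak]
    sd = diffs.std(ddof=1) if len(diffs) > 1 else 0.0
    d = float(diffs.mean() / sd) if sd > 0 else 0.0
    return CategoryResult(
        weak_mean=weak_mean,
        strong_mean=strong_mean,
        diff=perm.observed,
        p=perm.p,
        d=d,
        n_perm=perm.n_perm,
        tail=tail,
    )


def drift_check(power: np.ndarray, trial_order: np.ndarray | None = None) -> tuple[float, float]:
    """Slow-drift check: Pearson rho of power against trial order, with the
    two-sided p from the t transform t = rho * sqrt((n-2) / (1-rho**2))."""
    power = np.asarray(power, dtype=float)
    if trial_order is None:
        trial_order = np.arange(len(power))
    trial_order = np.asarray(trial_order, dtype=float)
    n = len(power)
    if n < 3:
        raise ValueError("need at least 3 trials")
    if power.std() == 0 or trial_order.std() == 0:
        return 0.0, 1.0
    rho = float(np.corrcoef(power, trial_order)[0, 1])
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2 * scipy.stats.t.sf(abs(t), n - 2))
    return rho, p


@dataclass
class StateDependenceResult:
    """One cell of the specificity battery: ROI x band x event type."""

    roi: str
    roi_kind: str
    band: str
    event_type: str
    n_trials: int
    rho: float
    p_perm_corr: float
    weak_mean: float
    strong_mean: float
    diff: float
    p_perm_cat: float
    d: float
    n_perm: int
    tail: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def specificity_battery(
    table: pd.DataFrame,
    roi_kinds: dict[str, str] | None = None,
    cfg: PermutationConfig | None = None,
    bands: tuple[str, ...] = ("alpha", "beta"),
    event_types: tuple[str, ...] = ("tms", "null"),
) -> pd.DataFrame:
    """Run correlation + category analyses over every ROI x band x event cell.

    ``table`` is a trial table with columns ``event_type``,
    ``alpha_power``, ``beta_power`` and one ``roi:<label>`` column per
    region. Cells whose trial count cannot support the category bins get
    NaN category fields rather than an error; missing crossings are
    reported absent. The output long-format frame carries one row per
    cell plus a ``significant`` flag at p < 0.05 for the correlation test.
    """
    cfg = cfg or PermutationConfig()
    roi_cols = [c for c in table.columns if c.startswith("roi:")]
    if not roi_cols:
        raise ValueError("trial table has no roi:<label> columns")
    if roi_kinds is None:
        roi_kinds = {c[4:]: "unknown" for c in roi_cols}
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for ev in event_types:
        sub = table[table["event_type"] == ev]
        for band in bands:
            pow_col = f"{band}_power"
            if pow_col not in table.columns or len(sub) < 3:
                continue
            tail = cfg.tail_for(band)
            power = sub[pow_col].to_numpy()
            for col in roi_cols:
                label = col[4:]
                betas = sub[col].to_numpy()
                rho = correlate_power_bold(power, betas)
                perm = permutation_test(power, betas, "corr", cfg, tail=tail, rng=rng)
                if 2 * cfg.bin_size <= len(sub):
                    cat = category_analysis(power, betas, cfg, tail=tail, rng=rng)
                    cat_fields = dict(
                        weak_mean=cat.weak_mean,
                        strong_mean=cat.strong_mean,
                        diff=cat.diff,
                        p_perm_cat=cat.p,
                        d=cat.d,
                    )
                else:
                    cat_fields = dict(
                        weak_mean=np.nan, strong_mean=np.nan, diff=np.nan,
                        p_perm_cat=np.nan, d=np.nan,
                    )
                rows.append(
                    StateDependenceResult(
                        roi=label,
                        roi_kind=roi_kinds.get(label, "unknown"),
                        band=band,
                        event_type=ev,
                        n_trials=len(sub),
                        rho=rho,
                        p_perm_corr=perm.p,
                        n_perm=perm.n_perm,
                        tail=tail,
                        **cat_fields,
                    ).to_dict()
                )
    out = pd.DataFrame(rows)
    if len(out):
        out["significant"] = out["p_perm_corr"] < 0.05
    return out
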