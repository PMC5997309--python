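"""Feather stable-isotope statistics and geographic assignment.

The assignment machinery is classical linear discriminant analysis in the
classification-function form: class g scores x with

    f_g(x) = (Sigma^-1 mu_g) . x - 1/2 mu_g' Sigma^-1 mu_g + ln pi_g

where Sigma is the pooled within-class covariance (divisor n - g) and the
priors pi_g are equal (uninformative) so their log-terms cancel in
comparisons. A bird is assigned to the class with the largest score. The
decision boundary between two classes is linear in (d15N, d13C).

Also here: the delta-notation conversion, the pseudo-replication-aware 70/30
train/test split, per-class correct-classification summaries with
sample-size-weighted totals, ANOVA / Kruskal-Wallis group comparisons with
compact-letter post-hoc displays, standard ellipse areas (SEA, SEAc and a
conjugate-posterior Bayesian variant), and the corpse-feather variability
screen used to reason about moult chronology.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LDAModel",
    "ConfusionSummary",
    "EllipseSummary",
    "GroupComparison",
    "delta_value",
    "fit_lda",
    "split_train_test",
    "classification_rates",
    "weighted_total",
    "group_comparison",
    "standard_ellipse",
    "feather_variability_summary",
]

ISOTOPE_COLS = ("d15N", "d13C")


def delta_value(r_sample, r_standard) -> np.ndarray:
    """Delta notation in per mil: (R_sample / R_standard - 1) * 1000."""
    r_sample = np.asarray(r_sample, dtype=float)
    r_standard = np.asarray(r_standard, dtype=float)
    if np.any(r_sample <= 0) or np.any(r_standard <= 0):
        raise ValueError("isotope ratios must be positive")
    return (r_sample / r_standard - 1.0) * 1000.0


@dataclass
class LDAModel:
    """Fitted linear discriminant model over (d15N, d13C)."""

    classes: list[str]
    means: np.ndarray  # (g, 2)
    pooled_cov: np.ndarray  # (2, 2)
    priors: np.ndarray  # (g,)
    coef: np.ndarray  # (g, 2)  Sigma^-1 mu_g
    intercept: np.ndarray  # (g,)  -1/2 mu_g' Sigma^-1 mu_g + ln pi_g

    def scores(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return x @ self.coef.T + self.intercept

    def predict(self, x: np.ndarray) -> np.ndarray:
        sc = self.scores(x)
        ties = np.isclose(sc.max(axis=1, keepdims=True), sc).sum(axis=1) > 1
        if ties.any():
            warnings.warn("tied discriminant scores: assigning first class")
        return np.asarray(self.classes)[np.argmax(sc, axis=1)]

    def classification_functions(self, decimals: int = 1) -> dict[str, str]:
        """Human-readable per-class functions, coefficients at fixed precision."""
        out = {}
        for g, cls in enumerate(self.classes):
            a, b = np.round(self.coef[g], decimals)
            c = np.round(self.intercept[g], decimals)
            out[cls] = (
                f"{a:+.{decimals}f}*d15N {b:+.{decimals}f}*d13C {c:+.{decimals}f}"
            )
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": self.classes,
                "means": self.means.tolist(),
                "pooled_cov": self.pooled_cov.tolist(),
                "priors": self.priors.tolist(),
                "coef": self.coef.tolist(),
                "intercept": self.intercept.tolist(),
                "functions": self.classification_functions(),
            },
            indent=2,
        )


def fit_lda(
    samples: pd.DataFrame,
    label_col: str,
    value_cols: tuple[str, str] = ISOTOPE_COLS,
) -> LDAModel:
    """Fit the classification-function LDA with equal priors.

    Pooled within-class covariance uses divisor n - g. Raises on fewer than
    two classes, classes with under 3 samples, or a singular pooled
    covariance (e.g. collinear isotope values).
    """
    labels = samples[label_col].astype(str)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    x = samples.loc[:, list(value_cols)].to_numpy(dtype=float)
    n, p = x.shape
    g = len(classes)
    means = np.empty((g, p))
    ssw = np.zeros((p, p))
    for i, cls in enumerate(classes):
        xi = x[(labels == cls).to_numpy()]
        if len(xi) < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 samples")
        means[i] = xi.mean(axis=0)
        dev = xi - means[i]
        ssw += dev.T @ dev
    pooled = ssw / (n - g)
    try:
        inv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular pooled covariance") from exc
    if np.linalg.cond(pooled) > 1e12:
        raise ValueError("singular pooled covariance")
    priors = np.full(g, 1.0 / g)
    coef = means @ inv
    intercept = -0.5 * np.einsum("ij,ij->i", coef, means) + np.log(priors)
    return LDAModel(classes, means, pooled, priors, coef, intercept)


def split_train_test(
    samples: pd.DataFrame,
    train_frac: float = 0.70,
    rng_seed: int = 0,
    label_col: str = "area",
    bird_col: str = "bird_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pseudo-replication-aware 70/30 split.

    The training set holds at most one record per bird (a random choice among
    a bird's repeats); all remaining records go to testing. Then, per class,
    if testing holds less than ``1 - train_frac`` of that class's records,
    random records migrate from training to testing until it does. The split
    is a pure function of the seed.
    """
    rng = np.random.default_rng(rng_seed)
    counts = samples[label_col].value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with fewer than 2 records: {bad}")
    train_idx: list[int] = []
    test_idx: list[int] = []
    for _, grp in samples.groupby(bird_col, sort=True):
        pick = grp.index[rng.integers(len(grp))]
        train_idx.append(pick)
        test_idx.extend(i for i in grp.index if i != pick)
    train = samples.loc[sorted(train_idx)]
    test = samples.loc[sorted(test_idx)]
    target = 1.0 - train_frac
    for cls in sorted(samples[label_col].astype(str).unique()):
        total = int((samples[label_col] == cls).sum())
        need = int(np.ceil(np.round(target * total, 9)))
        have = int((test[label_col] == cls).sum())
        while have < need:
            pool = train.index[train[label_col] == cls].to_numpy()
            if pool.size <= 1:
                break
            move = pool[rng.integers(pool.size)]
            test = pd.concat([test, train.loc[[move]]])
            train = train.drop(index=move)
            have += 1
    return train.sort_index(), test.sort_index()


@dataclass
class ConfusionSummary:
    """Per-class and total correct-classification rates (%), train and test."""

    classes: list[str]
    n_train: dict[str, int]
    n_test: dict[str, int]
    pct_train: dict[str, float]
    pct_test: dict[str, float]
    total_train: float = field(init=False)
    total_test: float = field(init=False)

    def __post_init__(self):
        self.total_train = weighted_total(
            [self.pct_train[c] for c in self.classes],
            [self.n_train[c] for c in self.classes],
        )
        self.total_test = weighted_total(
            [self.pct_test[c] for c in self.classes],
            [self.n_test[c] for c in self.classes],
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": c,
                "n_train": self.n_train[c],
                "n_test": self.n_test[c],
                "pct_train": self.pct_train[c],
                "pct_test": self.pct_test[c],
            }
            for c in self.classes
        ]
        rows.append(
            {
                "class": "Total",
                "n_train": sum(self.n_train.values()),
                "n_test": sum(self.n_test.values()),
                "pct_train": self.total_train,
                "pct_test": self.total_test,
            }
        )
        return pd.DataFrame(rows)


def weighted_total(rates, ns) -> float:
    """Sample-size-weighted mean of per-class rates."""
    rates = np.asarray(rates, dtype=float)
    ns = np.asarray(ns, dtype=float)
    return float((rates * ns).sum() / ns.sum())


def classification_rates(
    model: LDAModel,
    train: pd.DataFrame,
    test: pd.DataFrame,
    label_col: str = "area",
    value_cols: tuple[str, str] = ISOTOPE_COLS,
) -> ConfusionSummary:
    """Correct-classification percentages per class, plus weighted totals."""
    out: dict[str, dict] = {"n": {}, "nt": {}, "pt": {}, "pe": {}}
    for cls in model.classes:
        tr = train[train[label_col] == cls]
        te = test[test[label_col] == cls]
        if len(te) == 0:
            raise ValueError(f"empty test class {cls!r}")
        pred_tr = model.predict(tr.loc[:, list(value_cols)].to_numpy())
        pred_te = model.predict(te.loc[:, list(value_cols)].to_numpy())
        out["n"][cls] = len(tr)
        out["nt"][cls] = len(te)
        out["pt"][cls] = 100.0 * float((pred_tr == cls).mean()) if len(tr) else np.nan
        out["pe"][cls] = 100.0 * float((pred_te == cls).mean())
    return ConfusionSummary(
        classes=list(model.classes),
        n_train=out["n"],
        n_test=out["nt"],
        pct_train=out["pt"],
        pct_test=out["pe"],
    )


@dataclass
class GroupComparison:
    """One univariate group test with a compact letter display."""

    test: str  # "anova" or "kruskal_wallis"
    statistic: float
    df: tuple[int, int] | int
    p_value: float
    letters: dict[str, str]


def _compact_letters(groups: list[str], differ: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; every pair in
    ``differ`` shares no letter.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in sorted(differ):
        new_sets = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb subsets
        letter_sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if s and not any(s <= t for t in letter_sets):
                letter_sets.append(s)
    letter_sets.sort(key=lambda s: min(groups.index(g) for g in s))
    letters = {g: "" for g in groups}
    for i, s in enumerate(letter_sets):
        ch = chr(ord("a") + i)
        for g in s:
            letters[g] += ch
    return letters


def _dunn_pairs(values: list[np.ndarray], groups: list[str], alpha: float) -> set:
    """Dunn's z-test on mean ranks with tie correction and Bonferroni."""
    all_vals = np.concatenate(values)
    n_tot = len(all_vals)
    ranks = stats.rankdata(all_vals)
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_tot - 1))
    start = 0
    mean_ranks = []
    for v in values:
        mean_ranks.append(ranks[start : start + len(v)].mean())
        start += len(v)
    m = len(groups) * (len(groups) - 1) // 2
    differ = set()
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(
                (n_tot * (n_tot + 1) / 12.0 - tie_term)
                * (1.0 / len(values[i]) + 1.0 / len(values[j]))
            )
            z = abs(mean_ranks[i] - mean_ranks[j]) / se
            p = min(1.0, 2.0 * (1.0 - stats.norm.cdf(z)) * m)
            if p < alpha:
                differ.add(tuple(sorted((groups[i], groups[j]))))
    return differ


def group_comparison(
    samples: pd.DataFrame,
    value_col: str,
    group_col: str,
    test: str = "auto",
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way ANOVA + Tukey HSD, or Kruskal-Wallis + Dunn, with letters.

    ``test="auto"`` picks Kruskal-Wallis when any group fails a Shapiro-Wilk
    normality check at ``alpha``. Groups sharing no letter differ at
    ``alpha``.
    """
    groups = sorted(samples[group_col].astype(str).unique())
    values = [
        samples.loc[samples[group_col].astype(str) == g, value_col].to_numpy(dtype=float)
        for g in groups
    ]
    if len(groups) < 2 or any(len(v) < 3 for v in values):
        raise ValueError("need >= 2 groups with >= 3 observations each")
    if test == "auto":
        normal = True
        for v in values:
            if np.ptp(v) == 0:
                continue  # constant group: Shapiro undefined, treat as non-normal data
            if stats.shapiro(v).pvalue < alpha:
                normal = False
        test = "anova" if normal else "kruskal"
    if test == "anova":
        if all(np.ptp(v) == 0 for v in values):
            warnings.warn("zero within-group variance: F degenerate")
            means = [v.mean() for v in values]
            if np.ptp(means) == 0:
                return GroupComparison(
                    "anova", 0.0, (len(groups) - 1, sum(map(len, values)) - len(groups)), 1.0,
                    {g: "a" for g in groups},
                )
        f, p = stats.f_oneway(*values)
        df = (len(groups) - 1, sum(map(len, values)) - len(groups))
        differ = set()
        if len(groups) > 2:
            hsd = stats.tukey_hsd(*values)
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    if hsd.pvalue[i, j] < alpha:
                        differ.add(tuple(sorted((groups[i], groups[j]))))
        elif p < alpha:
            differ.add(tuple(sorted(groups[:2])))
        return GroupComparison("anova", float(f), df, float(p), _compact_letters(groups, differ))
    if test == "kruskal":
        h, p = stats.kruskal(*values)
        differ = _dunn_pairs(values, groups, alpha) if p < alpha else set()
        return GroupComparison(
            "kruskal_wallis", float(h), len(groups) - 1, float(p), _compact_letters(groups, differ)
        )
    raise ValueError(f"unknown test {test!r}")


@dataclass
class EllipseSummary:
    """Standard ellipse of a bivariate isotope sample."""

    label: str
    n: int
    sea: float  # per mil squared
    seac: float
    semi_axes: tuple[float, float]
    orientation: float  # radians, major axis vs d15N axis
    posterior_sea: np.ndarray | None = None


def standard_ellipse(
    samples: pd.DataFrame | np.ndarray,
    label: str = "",
    bayesian: bool = False,
    n_draws: int = 1000,
    rng_seed: int = 0,
    value_cols: tuple[str, str] = ISOTOPE_COLS,
) -> EllipseSummary:
    """Standard ellipse area SEA = pi sqrt(l1 l2) and small-sample SEAc.

    SEAc multiplies SEA by (n-1)/(n-2). With ``bayesian=True``, draws of the
    covariance from the conjugate normal-inverse-Wishart posterior (vague
    prior: nu0 = 3, prior scale = 0.01 x sample covariance, mean at the
    sample mean)
    are mapped to SEAs, giving a posterior distribution of niche width.
    """
    if isinstance(samples, pd.DataFrame):
        x = samples.loc[:, list(value_cols)].to_numpy(dtype=float)
    else:
        x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples for an ellipse")
    cov = np.cov(x.T, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval.min() <= 1e-12:
        raise ValueError("degenerate (collinear) samples")
    sea = float(np.pi * np.sqrt(eigval[0] * eigval[1]))
    seac = sea * (n - 1) / (n - 2)
    major = eigvec[:, int(np.argmax(eigval))]
    orientation = float(np.arctan2(major[1], major[0]))
    posterior = None
    if bayesian:
        rng = np.random.default_rng(rng_seed)
        nu0 = 3.0
        lambda0 = 0.01 * cov
        xbar = x.mean(axis=0)
        dev = x - xbar
        s_n = dev.T @ dev
        # prior mean centred on the sample mean, so the kappa cross-term vanishes
        lam_n = lambda0 + s_n
        nu_n = nu0 + n
        draws = stats.invwishart.rvs(df=nu_n, scale=lam_n, size=n_draws, random_state=rng)
        ev = np.linalg.eigvalsh(draws)
        posterior = np.pi * np.sqrt(np.clip(ev[:, 0] * ev[:, 1], 0, None))
    return EllipseSummary(label, n, sea, seac, (float(np.sqrt(eigval.max())), float(np.sqrt(eigval.min()))), orientation, posterior)


def feather_variability_summary(
    corpse_samples: pd.DataFrame,
    sd_multiple: float = 2.0,
    value_col: str = "d15N",
) -> pd.DataFrame:
    """Per-feather, per-colony mean/SD table with a moult-chronology flag.

    A feather whose pooled SD exceeds ``sd_multiple`` times the pooled P1 SD
    is flagged ``high_variability``: its growth plausibly spans distinct
    isotopic environments (late moult in area-specific non-breeding grounds),
    whereas low-variability feathers were grown in a shared environment.
    """
    per = (
        corpse_samples.groupby(["feather", "colony"])[["d15N", "d13C"]]
        .agg(["mean", "std"])
    )
    per.columns = ["_".join(c) for c in per.columns]
    per = per.reset_index()
    pooled = corpse_samples.groupby("feather")[value_col].std()
    ref = pooled.get("P1", np.nan)
    per["high_variability"] = per["feather"].map(
        lambda f: bool(np.isfinite(ref) and pooled[f] > sd_multiple * ref)
    )
    return per
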