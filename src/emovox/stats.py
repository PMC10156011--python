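"""Confusion-matrix metrics and the inferential pipeline.

For 4-alternative emotion categorization, raw accuracy (the biased hit
rate H_b) confounds sensitivity with response bias: a listener who
answers "sad" on every trial scores perfectly on sad stimuli. Wagner's
unbiased hit rate corrects for label overuse:

    H_b(i) = n_ii / row_i
    H_u(i) = n_ii^2 / (row_i * col_i)
    p_c(i) = row_i * col_i / N^2

where ``row_i`` is the number of trials of true category *i*, ``col_i``
the number of times label *i* was used, and ``N`` the grand total. Under
random responding the expected H_u equals the chance proportion p_c, so
H_u is tested against p_c with paired t-tests. For comparison across
studies with different numbers of response alternatives the biased hit
rate is also rescaled to the proportion index

    pi = H_b (k-1) / (1 + H_b (k-2))

which maps chance (1/k) to 0.5 and perfect decoding to 1 for any k.

The language-familiarity test is a 2 x 2 mixed ANOVA — stimulus language
(native vs foreign) within subjects, participant group between — whose
Group x Language interaction is the LFE signature; effect sizes are
partial eta squared and Cohen's d for the follow-up paired contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "ConfusionTable",
    "EmotionMetrics",
    "AnovaEffect",
    "AnovaResult",
    "ContrastResult",
    "confusion_matrix",
    "hit_rates",
    "proportion_index",
    "chance_test",
    "paired_contrast",
    "mixed_anova_2x2",
    "exp2_accuracy",
]


@dataclass(frozen=True)
class ConfusionTable:
    """k x k stimulus-by-response counts with category labels."""

    counts: np.ndarray
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion counts must be square")
        if counts.shape[0] < 2:
            raise ValueError("need at least 2 categories")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.number):
            raise ValueError("counts must be nonnegative")
        if counts.sum() <= 0:
            raise ValueError("confusion table is empty")
        if len(self.categories) != counts.shape[0]:
            raise ValueError("category labels must match table size")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "categories", tuple(self.categories))

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class EmotionMetrics:
    """Per-category decoding metrics derived from one confusion table.

    All proportions in [0, 1]; ``pi`` is the proportion index computed
    from H_b with k = number of categories.
    """

    categories: tuple[str, ...]
    h_biased: np.ndarray
    h_unbiased: np.ndarray
    p_chance: np.ndarray
    pi: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": self.categories,
                "H_b": self.h_biased,
                "pi": self.pi,
                "H_u": self.h_unbiased,
                "p_c": self.p_chance,
            }
        )


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float


@dataclass(frozen=True)
class AnovaResult:
    """Mixed-ANOVA table: between effect, within effect, interaction."""

    group: AnovaEffect
    within: AnovaEffect
    interaction: AnovaEffect

    def as_frame(self) -> pd.DataFrame:
        rows = [self.group, self.within, self.interaction]
        return pd.DataFrame(
            {
                "effect": [r.name for r in rows],
                "F": [r.F for r in rows],
                "df1": [r.df1 for r in rows],
                "df2": [r.df2 for r in rows],
                "p": [r.p for r in rows],
                "eta_p2": [r.eta_p2 for r in rows],
            }
        )


@dataclass(frozen=True)
class ContrastResult:
    t: float
    df: int
    p_raw: float
    alpha_bonferroni: float
    cohens_d: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_raw < self.alpha_bonferroni


# ---------------------------------------------------------------------------
# confusion metrics

def confusion_matrix(
    responses: pd.DataFrame,
    categories: tuple[str, ...] | None = None,
    **selector,
) -> ConfusionTable:
    """Tabulate (true_category x response_category) counts.

    ``selector`` keywords filter rows by equality on any column, e.g.
    ``confusion_matrix(df, participant_id=3, stimulus_language="FR",
    condition="normal")``.
    """
    df = responses
    for col, val in selector.items():
        df = df[df[col] == val]
    if df.empty:
        raise ValueError(f"no trials in the selected cell: {selector}")
    if categories is None:
        from .observers import CATEGORIES

        categories = CATEGORIES
    cats = list(categories)
    idx = {c: i for i, c in enumerate(cats)}
    counts = np.zeros((len(cats), len(cats)), dtype=np.int64)
    for true, resp in zip(df["true_category"], df["response_category"]):
        counts[idx[true], idx[resp]] += 1
    # rows without trials are permitted here; hit_rates rejects them where
    # the per-category metrics would be undefined
    return ConfusionTable(counts, tuple(cats))


def hit_rates(table: ConfusionTable) -> EmotionMetrics:
    """Wagner's biased/unbiased hit rates and chance proportions.

    Categories whose label was never used (zero column total) get
    ``H_u = 0``; a zero row total is an error (no trials of that
    category).
    """
    counts = table.counts.astype(np.float64)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    n = counts.sum()
    if np.any(row == 0):
        raise ValueError("every true category needs at least one trial")
    diag = np.diag(counts)
    h_b = diag / row
    with np.errstate(divide="ignore", invalid="ignore"):
        h_u = np.where(col > 0, diag**2 / (row * np.where(col > 0, col, 1.0)), 0.0)
    p_c = row * col / n**2
    k = len(table.categories)
    pi = np.array([proportion_index(h, k) for h in h_b])
    return EmotionMetrics(table.categories, h_b, h_u, p_c, pi)


def proportion_index(h_b: float, k: int) -> float:
    """Rescale a k-alternative hit rate to a 0.5-chance / 1.0-perfect scale.

    ``pi = h_b (k-1) / (1 + h_b (k-2))``; chance performance ``h_b = 1/k``
    maps to 0.5 and ``h_b = 1`` to 1 for any number of alternatives k >= 2.
    """
    if not 0 <= h_b <= 1:
        raise ValueError("h_b must be a proportion in [0, 1]")
    if k < 2:
        raise ValueError("need at least 2 response categories")
    return h_b * (k - 1) / (1.0 + h_b * (k - 2))


# ---------------------------------------------------------------------------
# t-tests

def paired_contrast(
    x, y, alpha_family: float = 0.05, n_comparisons: int = 1
) -> ContrastResult:
    """Paired t-test with Cohen's d for dependent samples.

    ``d = mean(x - y) / sd(x - y)`` (sd with n-1 denominator); the
    Bonferroni-adjusted alpha for the stated family size is carried in
    the result. Zero-variance differences are flagged degenerate.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D paired samples")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y
    sd = float(np.std(diff, ddof=1))
    alpha = alpha_family / n_comparisons
    if sd == 0.0:
        return ContrastResult(
            t=0.0 if np.allclose(diff, 0) else np.inf * np.sign(diff.mean()),
            df=x.size - 1,
            p_raw=1.0 if np.allclose(diff, 0) else 0.0,
            alpha_bonferroni=alpha,
            cohens_d=0.0,
            degenerate=True,
        )
    t, p = sstats.ttest_rel(x, y)
    d = float(diff.mean()) / sd
    return ContrastResult(float(t), x.size - 1, float(p), alpha, d)


def chance_test(
    h_u_per_participant, p_c_per_participant, alpha_family: float = 0.05,
    n_comparisons: int = 12,
) -> ContrastResult:
    """Test unbiased hit rates against their chance proportions.

    One-sample structure (paired by participant), Bonferroni-corrected
    across the comparison family (default: 12 comparisons — 4 categories
    x 3 native/foreign/control cells).
    """
    return paired_contrast(
        h_u_per_participant, p_c_per_participant, alpha_family, n_comparisons
    )


# ---------------------------------------------------------------------------
# mixed ANOVA

def mixed_anova_2x2(
    data: pd.DataFrame,
    dv: str = "y",
    subject: str = "subject",
    between: str = "group",
    within: str = "language",
) -> AnovaResult:
    """Two-way mixed ANOVA: one 2-level between factor, one 2-level
    within factor, via explicit sums of squares.

    Expects one observation per subject per within level (cell means).
    The between effect is tested against subject-within-group variation
    and the within and interaction effects against the subject-by-within
    residual; partial eta squared is ``SS_effect / (SS_effect +
    SS_error)`` with each effect's own error term. Handles unequal group
    sizes (weighted/Type II sums of squares, which coincide with Type III
    in this two-factor design with one observation per cell).
    """
    df = data[[subject, between, within, dv]].dropna()
    groups = sorted(df[between].unique())
    levels = sorted(df[within].unique())
    if len(groups) != 2 or len(levels) != 2:
        raise ValueError("mixed_anova_2x2 requires exactly 2 groups and 2 within levels")
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("every subject needs one value per within level")
    y = wide.to_numpy()  # subjects x 2
    grp = wide.index.get_level_values(between).to_numpy()
    n_i = np.array([(grp == g).sum() for g in groups])
    if np.any(n_i < 2):
        raise ValueError("need at least 2 subjects per group")
    n_subj = y.shape[0]
    J = 2
    grand = y.mean()

    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[grp == g].mean() for g in groups])
    ss_between_subj = J * np.sum((subj_means - grand) ** 2)
    ss_group = J * np.sum(n_i * (group_means - grand) ** 2)
    ss_subj_err = ss_between_subj - ss_group

    level_means = y.mean(axis=0)
    ss_within_factor = n_subj * np.sum((level_means - grand) ** 2)
    cell_means = np.array([[y[grp == g, j].mean() for j in range(J)] for g in groups])
    ss_cells = np.sum(n_i[:, None] * (cell_means - grand) ** 2)
    ss_interaction = ss_cells - ss_group - ss_within_factor
    ss_total = np.sum((y - grand) ** 2)
    ss_within_err = ss_total - ss_between_subj - ss_within_factor - ss_interaction

    df_group, df_subj = 1, n_subj - 2
    df_within, df_werr = 1, n_subj - 2

    def effect(name, ss_eff, ss_err, df1, df2):
        ms_eff, ms_err = ss_eff / df1, ss_err / df2
        if ms_err <= 0:
            F = 0.0 if ms_eff == 0 else np.inf
            p = 1.0 if ms_eff == 0 else 0.0
        else:
            F = ms_eff / ms_err
            p = float(sstats.f.sf(F, df1, df2))
        denom = ss_eff + ss_err
        eta = float(ss_eff / denom) if denom > 0 else 0.0
        return AnovaEffect(name, float(F), df1, df2, p, eta)

    return AnovaResult(
        group=effect(between, ss_group, ss_subj_err, df_group, df_subj),
        within=effect(within, ss_within_factor, ss_within_err, df_within, df_werr),
        interaction=effect(
            f"{between} * {within}", ss_interaction, ss_within_err, df_within, df_werr
        ),
    )


# ---------------------------------------------------------------------------
# experiment-2 accuracy

def exp2_accuracy(
    responses: pd.DataFrame,
    by: tuple[str, ...] = ("participant_id", "group", "stimulus_language", "condition"),
) -> pd.DataFrame:
    """Per-cell percent-correct table for the pitch-change detection task.

    Returns one row per design cell with the mean of ``correct`` as
    ``accuracy`` (proportion). Default cells: participant x language x
    condition (8 stimulus cells per participant).
    """
    if responses.empty:
        raise ValueError("empty response table")
    out = (
        responses.groupby(list(by), sort=True)["correct"]
        .agg(accuracy="mean", n_trials="size")
        .reset_index()
    )
    return out
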