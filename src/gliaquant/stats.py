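"""Analysis-of-variance comparisons used by the quantification pipeline.

Two designs: a one-way ANOVA between independent groups (e.g. CB2 density
in marker-positive vs -negative areas), and a two-way mixed ANOVA with
genotype as the between-subject factor and cell marker as the repeated
(within-subject) measure.  Pairwise follow-ups use Fisher's LSD: plain t
tests on the omnibus error term, no multiplicity correction, applied only
after a significant omnibus effect (alpha = 0.05).  No sphericity
correction is applied.

The unit of replication (image/field vs animal) is the caller's choice:
these routines see only the table they are given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["AnovaResult", "one_way_anova", "two_way_mixed_anova", "lsd_posthoc"]

ALPHA = 0.05


@dataclass
class AnovaResult:
    """Per-effect F table plus the error terms needed for post-hocs."""

    design: str
    rows: list[dict] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows).set_index("effect")

    def effect(self, name: str) -> dict:
        for row in self.rows:
            if row["effect"] == name:
                return row
        raise KeyError(f"no effect {name!r} in {self.design} result")

    @property
    def residual_ms(self) -> float:
        return self.rows[-1]["ms_error"]


def _f_row(effect: str, ss: float, df: int, ss_err: float, df_err: int) -> dict:
    ss, ss_err = max(ss, 0.0), max(ss_err, 0.0)
    ms, ms_err = ss / df, ss_err / df_err
    if ms_err > 0:
        f = ms / ms_err
        p = float(sps.f.sf(f, df, df_err))
    else:  # zero residual: any effect at all is infinitely unlikely by chance
        f = np.inf if ms > 0 else 0.0
        p = 0.0 if ms > 0 else 1.0
    return {
        "effect": effect, "ss": ss, "df_num": df, "df_den": df_err,
        "ms": ms, "ms_error": ms_err, "F": f, "p": p,
    }


def one_way_anova(groups: list) -> AnovaResult:
    """Between-groups ANOVA from lists of values per group.

    The usual between/within sum-of-squares decomposition; equivalent to
    the pooled two-sample t test (F = t^2) when there are two groups.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = len(groups) - 1, len(allv) - len(groups)
    res = AnovaResult(design="one_way")
    res.rows.append(_f_row("group", ss_between, df_b, ss_within, df_w))
    return res


def two_way_mixed_anova(
    data: pd.DataFrame,
    value: str = "value",
    subject: str = "subject",
    between: str = "genotype",
    within: str = "marker",
) -> AnovaResult:
    """Mixed-design ANOVA: one between-subject and one repeated factor.

    Every subject must carry every within-factor level exactly once
    (listwise completeness); between-group sizes may differ.  The
    between-factor F uses the subjects-within-groups mean square as error;
    the within factor and the interaction use the within-cell residual
    (subject x within interaction within groups).
    """
    df = data[[subject, between, within, value]].dropna()
    wide = df.pivot_table(index=[between, subject], columns=within,
                          values=value, aggfunc="first")
    if wide.isna().any().any():
        raise ValueError("unbalanced within factor: every subject needs all levels")
    counts = df.groupby([subject])[within].count()
    if (counts != wide.shape[1]).any():
        raise ValueError("duplicate or missing within-level measurements")
    groups = wide.index.get_level_values(0)
    if any((groups == g).sum() < 2 for g in set(groups)):
        raise ValueError("need >= 2 subjects per between-factor level")

    x = wide.to_numpy(dtype=float)          # subjects x within-levels
    n_subj, m = x.shape
    glabels = np.asarray(groups)
    glevels = list(dict.fromkeys(glabels))
    ng = len(glevels)
    grand = x.mean()

    subj_means = x.mean(axis=1)
    ss_between_subj = m * ((subj_means - grand) ** 2).sum()
    ss_g = m * sum((glabels == g).sum() * (x[glabels == g].mean() - grand) ** 2
                   for g in glevels)
    ss_subj_within = ss_between_subj - ss_g

    marker_means = x.mean(axis=0)
    ss_w = n_subj * ((marker_means - grand) ** 2).sum()
    ss_inter = sum(
        (glabels == g).sum()
        * ((x[glabels == g].mean(axis=0) - x[glabels == g].mean()
            - marker_means + grand) ** 2).sum()
        for g in glevels
    )
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_g - ss_subj_within - ss_w - ss_inter

    df_g, df_sw = ng - 1, n_subj - ng
    df_w, df_i = m - 1, (ng - 1) * (m - 1)
    df_err = (n_subj - ng) * (m - 1)
    res = AnovaResult(design="two_way_mixed")
    res.rows.append(_f_row(between, ss_g, df_g, ss_subj_within, df_sw))
    res.rows.append(_f_row(within, ss_w, df_w, ss_err, df_err))
    res.rows.append(_f_row(f"{between}*{within}", ss_inter, df_i, ss_err, df_err))
    return res


def lsd_posthoc(
    anova: AnovaResult,
    cell_means: dict[str, float],
    ns: dict[str, int],
    effect: str | None = None,
) -> pd.DataFrame:
    """Fisher's least-significant-difference pairwise comparisons.

    For each pair of cells, t = (m_a - m_b) / sqrt(MS_err (1/n_a + 1/n_b))
    with the error mean square and df of the omnibus effect; p is the
    two-sided t probability with no multiplicity correction (that is the
    LSD).  Symmetric in pair order.
    """
    row = anova.effect(effect) if effect else anova.rows[0]
    ms_err, df_err = row["ms_error"], row["df_den"]
    if df_err < 1:
        raise ValueError("error term has no degrees of freedom")
    out = []
    for a, b in combinations(cell_means, 2):
        se = np.sqrt(ms_err * (1 / ns[a] + 1 / ns[b]))
        t = (cell_means[a] - cell_means[b]) / se if se > 0 else 0.0
        p = float(2 * sps.t.sf(abs(t), df_err)) if se > 0 else 1.0
        out.append({"a": a, "b": b, "diff": cell_means[a] - cell_means[b],
                    "t": t, "df": df_err, "p": p})
    return pd.DataFrame(out)
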