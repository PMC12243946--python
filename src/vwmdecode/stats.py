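"""Group-level statistical battery over participants.

t tests against chance are one-sample and one-tailed (only above-chance
decoding is meaningful); cross-decoding-drop tests are paired and one-tailed
(the drop is either null or positive); sector pairwise comparisons are paired
and two-tailed.  Multiple comparisons are corrected with the
Benjamini-Hochberg step-up procedure within explicit families — the tests of
the same type within each ROI or sector, and the three sector-pair tests.
Two-way repeated-measures ANOVAs (subject as random blocking factor, no
sphericity correction) assess main effects and interactions, e.g. trial type
(with vs without distractors) x decoding (within vs cross) per ROI and per
sector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats


@dataclass(frozen=True)
class TestSpec:
    """What a t test is, for bookkeeping and correction.

    ``kind``: one_sample_vs_chance | paired_drop | paired_two_tailed |
    one_sample_vs_one.  ``family`` groups tests corrected together.
    Tails are fixed by the kind, never inferred from the data's sign.
    """

    kind: str
    family: str
    mu: float = 0.5

    @property
    def tail(self) -> str:
        return {
            "one_sample_vs_chance": "greater",
            "paired_drop": "greater",  # within - cross expected >= 0
            "paired_two_tailed": "two-sided",
            "one_sample_vs_one": "less",  # ratio expected <= 1
        }[self.kind]


def t_tests(
    values: np.ndarray,
    spec: TestSpec,
    paired_with: np.ndarray | None = None,
) -> dict:
    """One t test: one-sample against ``spec.mu`` or paired against
    ``paired_with`` (ordered so a positive t means values > paired_with).

    Zero-variance input yields an undefined (NaN) statistic, reported as
    such rather than raised.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 participants")
    if spec.kind.startswith("paired") and paired_with is not None:
        d = x - np.asarray(paired_with, dtype=float)
    else:
        d = x - spec.mu
    scale = 1.0 + np.abs(d).max(initial=0.0)
    if np.std(d) <= 1e-12 * scale:
        # all-equal data: t = 0 (p = 0.5 one-tailed) when at the null mean,
        # otherwise the statistic is undefined and reported as NaN
        at_null = np.abs(d).max(initial=0.0) <= 1e-12 * scale
        t_val = 0.0 if at_null else float("nan")
        p_val = (0.5 if spec.tail != "two-sided" else 1.0) if at_null else float("nan")
        return {
            "kind": spec.kind, "family": spec.family,
            "t": t_val, "df": int(x.size - 1), "p": p_val, "n": int(x.size),
        }
    if spec.kind.startswith("paired"):
        if paired_with is None:
            raise ValueError(f"{spec.kind} requires a paired vector")
        y = np.asarray(paired_with, dtype=float)
        if y.shape != x.shape:
            raise ValueError("paired vectors must be matched")
        with np.errstate(invalid="ignore", divide="ignore"):
            res = scipy.stats.ttest_rel(x, y, alternative=spec.tail)
    else:
        if paired_with is not None:
            raise ValueError(f"{spec.kind} is one-sample")
        with np.errstate(invalid="ignore", divide="ignore"):
            res = scipy.stats.ttest_1samp(x, spec.mu, alternative=spec.tail)
    return {
        "kind": spec.kind,
        "family": spec.family,
        "t": float(res.statistic),
        "df": int(x.size - 1),
        "p": float(res.pvalue),
        "n": int(x.size),
    }


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, clipped at 1).

    NaN entries pass through unadjusted and do not count toward the family
    size.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def rm_anova_2way(
    values: np.ndarray,
    factor_names: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Two-way fully within-subject ANOVA on a (subjects, a, b) array.

    Each effect is tested against its own subject-interaction error term
    (MS_effect / MS_effect-by-subject).  No sphericity correction is applied.
    Factors with a single level contribute no testable effect; with b == 1
    and a == 2 the main-effect F equals the paired t squared.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 3:
        raise ValueError("values must be (subjects, levels_A, levels_B)")
    if np.isnan(y).any():
        raise ValueError("missing cells: the design must be complete and balanced")
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    A = y.mean(axis=(0, 2))
    B = y.mean(axis=(0, 1))
    AB = y.mean(axis=0)
    sA = y.mean(axis=2)
    sB = y.mean(axis=1)

    rows = []

    def effect(name, ss, df, ss_err, df_err):
        if df == 0 or df_err == 0:
            return
        ms, ms_err = ss / df, ss_err / df_err
        F = ms / ms_err if ms_err > 0 else np.inf
        p = float(scipy.stats.f.sf(F, df, df_err)) if np.isfinite(F) else 0.0
        rows.append(
            {"effect": name, "F": float(F), "df1": df, "df2": df_err,
             "p": p, "ss": float(ss), "ss_error": float(ss_err)}
        )

    ss_A = n * b * ((A - grand) ** 2).sum()
    ss_AS = b * ((sA - subj[:, None] - A[None, :] + grand) ** 2).sum()
    effect(factor_names[0], ss_A, a - 1, ss_AS, (a - 1) * (n - 1))

    ss_B = n * a * ((B - grand) ** 2).sum()
    ss_BS = a * ((sB - subj[:, None] - B[None, :] + grand) ** 2).sum()
    effect(factor_names[1], ss_B, b - 1, ss_BS, (b - 1) * (n - 1))

    ss_AB = n * ((AB - A[:, None] - B[None, :] + grand) ** 2).sum()
    resid = (
        y
        - sA[:, :, None]
        - sB[:, None, :]
        - AB[None, :, :]
        + subj[:, None, None]
        + A[None, :, None]
        + B[None, None, :]
        - grand
    )
    ss_ABS = (resid**2).sum()
    effect(
        f"{factor_names[0]} x {factor_names[1]}",
        ss_AB,
        (a - 1) * (b - 1),
        ss_ABS,
        (a - 1) * (b - 1) * (n - 1),
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the full battery


@dataclass
class StatReport:
    """All group-level tables, with raw and BH-adjusted p values."""

    vs_chance: pd.DataFrame
    drop: pd.DataFrame
    sector_pairwise: pd.DataFrame
    anova: pd.DataFrame
    alpha: float = 0.05
    notes: tuple[str, ...] = (
        "no sphericity correction applied to repeated-measures ANOVAs",
        "adjusted p values are Benjamini-Hochberg within the listed family",
    )


#: (within scheme, cross scheme, trial_set on the target side)
DEFAULT_COMPARISONS = (
    ("within_target_delay", "cross_distractor_to_target_delay", "with_distractors"),
    ("within_target_encoding", "cross_distractor_to_target_encoding", "with_distractors"),
)


def _adjust_within_families(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        df["p_adj"] = []
        return df
    df = df.copy()
    df["p_adj"] = np.nan
    for fam, idx in df.groupby("family").groups.items():
        df.loc[idx, "p_adj"] = bh_adjust(df.loc[idx, "p"].to_numpy())
    return df


def run_battery(
    decoding: pd.DataFrame,
    comparisons=DEFAULT_COMPARISONS,
    alpha: float = 0.05,
) -> StatReport:
    """The full statistical battery on a tidy decoding table.

    ``decoding`` needs columns participant, unit (ROI or sector name),
    level ('roi'|'sector'), scheme, trial_set, accuracy; one row per
    participant x unit x scheme x trial_set.
    """
    required = {"participant", "unit", "level", "scheme", "trial_set", "accuracy"}
    missing = required - set(decoding.columns)
    if missing:
        raise ValueError(f"decoding table missing columns: {sorted(missing)}")

    participants = sorted(decoding["participant"].unique())

    def cohort_values(unit, scheme, trial_set):
        sub = decoding[
            (decoding["unit"] == unit)
            & (decoding["scheme"] == scheme)
            & (decoding["trial_set"] == trial_set)
        ].set_index("participant")["accuracy"]
        absent = [p for p in participants if p not in sub.index]
        if absent:
            raise ValueError(
                f"incomplete cohort for unit={unit!r} scheme={scheme!r} "
                f"trial_set={trial_set!r}: missing participants {absent}"
            )
        return sub.loc[participants].to_numpy()

    vs_rows, drop_rows = [], []
    units = decoding[["unit", "level"]].drop_duplicates().itertuples(index=False)
    present = set(
        map(tuple, decoding[["unit", "scheme", "trial_set"]].drop_duplicates().to_numpy())
    )
    drop_by_unit: dict[tuple, dict[str, np.ndarray]] = {}
    for unit, level in units:
        for within_s, cross_s, tset in comparisons:
            if (unit, within_s, tset) not in present or (unit, cross_s, tset) not in present:
                continue
            fam = f"vs_chance/{level}/{unit}"
            w = cohort_values(unit, within_s, tset)
            c = cohort_values(unit, cross_s, tset)
            for scheme, vals in ((within_s, w), (cross_s, c)):
                row = t_tests(vals, TestSpec("one_sample_vs_chance", fam, mu=0.5))
                row.update(unit=unit, level=level, scheme=scheme, trial_set=tset,
                           mean=float(vals.mean()))
                vs_rows.append(row)
            dfam = f"drop/{level}/{unit}"
            row = t_tests(w, TestSpec("paired_drop", dfam), paired_with=c)
            row.update(unit=unit, level=level, within=within_s, cross=cross_s,
                       trial_set=tset, mean_drop=float((w - c).mean()))
            drop_rows.append(row)
            drop_by_unit.setdefault((level, f"{within_s}|{cross_s}"), {})[unit] = w - c

    vs_chance = _adjust_within_families(pd.DataFrame(vs_rows))
    drop = _adjust_within_families(pd.DataFrame(drop_rows))

    # sector pairwise comparisons of the drop (two-tailed, family of 3)
    pair_rows = []
    for (level, comp), by_unit in drop_by_unit.items():
        if level != "sector" or len(by_unit) < 2:
            continue
        sectors = sorted(by_unit)
        import itertools as _it

        for s1, s2 in _it.combinations(sectors, 2):
            fam = f"sector_pairs/{comp}"
            row = t_tests(
                by_unit[s1], TestSpec("paired_two_tailed", fam), paired_with=by_unit[s2]
            )
            row.update(comparison=comp, sector_1=s1, sector_2=s2, level=level)
            pair_rows.append(row)
    sector_pairwise = _adjust_within_families(pd.DataFrame(pair_rows))

    # per-unit trial-type x decoding ANOVA where both trial sets exist
    anova_rows = []
    units = decoding[["unit", "level"]].drop_duplicates().itertuples(index=False)
    for unit, level in units:
        cells = {}
        try:
            cells[("with", "within")] = cohort_values(unit, "within_target_delay", "with_distractors")
            cells[("with", "cross")] = cohort_values(
                unit, "cross_distractor_to_target_delay", "with_distractors"
            )
            cells[("without", "within")] = cohort_values(unit, "within_delay", "without_distractors")
            cells[("without", "cross")] = cohort_values(
                unit, "cross_to_no_distractor_targets", "without_distractors"
            )
        except ValueError:
            continue
        y = np.stack(
            [
                np.stack([cells[("with", "within")], cells[("with", "cross")]], axis=-1),
                np.stack([cells[("without", "within")], cells[("without", "cross")]], axis=-1),
            ],
            axis=1,
        )  # (n, trial_type=2, decoding=2)
        tab = rm_anova_2way(y, factor_names=("trial_type", "decoding"))
        tab.insert(0, "unit", unit)
        tab.insert(1, "level", level)
        anova_rows.append(tab)
    anova = (
        pd.concat(anova_rows, ignore_index=True)
        if anova_rows
        else pd.DataFrame(columns=["unit", "level", "effect", "F", "df1", "df2", "p"])
    )
    return StatReport(
        vs_chance=vs_chance,
        drop=drop,
        sector_pairwise=sector_pairwise,
        anova=anova,
        alpha=alpha,
    )
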