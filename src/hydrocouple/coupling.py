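"""Correlations, coupling ratios, sigma-based fluctuation groups, summary.

The headline quantities mirror the standard workflow for protein-hydration
coupling studies: Spearman correlations between residue descriptors (RMSF,
SASA) and the mean hydration-water order parameter, the relaxation-time
ratio tau_RMSD / tau_zeta (>> 1 means the residue relaxes far more slowly
than its hydration water, i.e. weak coupling), and a four-way fluctuation
classification G1-G4 by whether sigma_RMSD and sigma_zeta exceed their
respective means:

    G1: sigma_RMSD > mean, sigma_zeta <= mean   (flexible residue, calm water)
    G2: both above their means                  (both fluctuate)
    G3: both at or below their means            (both stable)
    G4: sigma_RMSD <= mean, sigma_zeta > mean   (calm residue, fluctuating water)

"Exceeds" is strict; residues equal to the mean fall in the lower group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ClassificationError, ConfigurationError, \
    UndefinedCorrelationError

GROUP_LABELS = ("G1", "G2", "G3", "G4")
CLASS_LABELS = ("non-polar", "polar", "charged")


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ConfigurationError("paired arrays must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson on mid-ranks, ties averaged).

    Pairs with undefined entries are dropped first; fewer than 3 remaining
    pairs, or zero rank variance, raise UndefinedCorrelationError.
    """
    xs, ys = _paired(x, y)
    if len(xs) < 3:
        raise UndefinedCorrelationError(
            f"need >= 3 complete pairs, have {len(xs)}"
        )
    if np.unique(xs).size < 2 or np.unique(ys).size < 2:
        raise UndefinedCorrelationError("zero rank variance")
    rho = stats.spearmanr(xs, ys).statistic
    return float(rho)


def linear_fit(x, y) -> tuple[float, float]:
    """Ordinary-least-squares slope and intercept on complete pairs."""
    xs, ys = _paired(x, y)
    if len(xs) < 2:
        raise UndefinedCorrelationError("need >= 2 complete pairs")
    if np.ptp(xs) == 0:
        raise UndefinedCorrelationError("x is constant; fit is degenerate")
    res = stats.linregress(xs, ys)
    return float(res.slope), float(res.intercept)


def classify_sigma_groups(
    sigma_rmsd: pd.Series,
    sigma_zeta: pd.Series,
) -> tuple[pd.Series, dict[str, float]]:
    """G1-G4 labels per residue plus the group fractions.

    Only residues with both sigmas defined are classified; the two means
    are taken over exactly those residues.
    """
    df = pd.DataFrame({"sr": sigma_rmsd, "sz": sigma_zeta}).dropna()
    if len(df) < 2:
        raise ClassificationError(
            "need at least 2 residues with both sigmas defined"
        )
    m_r = df["sr"].mean()
    m_z = df["sz"].mean()
    hi_r = df["sr"] > m_r
    hi_z = df["sz"] > m_z
    labels = pd.Series("G3", index=df.index, name="group")
    labels[hi_r & ~hi_z] = "G1"
    labels[hi_r & hi_z] = "G2"
    labels[~hi_r & hi_z] = "G4"
    n = len(labels)
    fractions = {g: float((labels == g).sum()) / n for g in GROUP_LABELS}
    return labels, fractions


def class_composition(
    groups: pd.Series,
    classes: pd.Series,
) -> pd.DataFrame:
    """Fraction of non-polar / polar / charged residues within each group.

    Residues of the excluded class (glycine) are dropped; a group with no
    classified residue gets a NaN row.
    """
    df = pd.DataFrame({"group": groups, "class": classes}).dropna()
    df = df[df["class"].isin(CLASS_LABELS)]
    out = pd.DataFrame(
        np.nan, index=list(GROUP_LABELS), columns=list(CLASS_LABELS)
    )
    for g in GROUP_LABELS:
        sub = df[df["group"] == g]
        if len(sub):
            counts = sub["class"].value_counts()
            for c in CLASS_LABELS:
                out.loc[g, c] = counts.get(c, 0) / len(sub)
    out.index.name = "group"
    return out


def build_summary(
    descriptors: pd.DataFrame,
    mean_zeta: pd.Series,
    sigma_zeta: pd.Series,
    sigma_rmsd: pd.Series,
    tau_zeta: pd.Series,
    tau_rmsd: pd.Series,
) -> tuple[pd.DataFrame, dict]:
    """Join all per-residue quantities and compute headline statistics.

    Parameters are keyed by internal residue index; ``descriptors`` must
    carry columns name / class / rmsf / sasa.  Returns the residue summary
    table and a dict of headline statistics (Spearman correlations, OLS
    slopes, per-class means and medians, group fractions and composition,
    and the fraction of residues whose coupling ratio exceeds 1).
    """
    if descriptors.index.has_duplicates:
        raise ConfigurationError("duplicate residue keys in descriptor table")
    table = descriptors.copy()
    for col, ser in (
        ("mean_zeta", mean_zeta),
        ("sigma_zeta", sigma_zeta),
        ("sigma_rmsd", sigma_rmsd),
        ("tau_zeta", tau_zeta),
        ("tau_rmsd", tau_rmsd),
    ):
        if ser is not None and pd.Index(ser.index).has_duplicates:
            raise ConfigurationError(f"duplicate residue keys in {col}")
        table[col] = ser
    table["ratio"] = table["tau_rmsd"] / table["tau_zeta"]

    groups, fractions = classify_sigma_groups(
        table["sigma_rmsd"], table["sigma_zeta"]
    )
    table["group"] = groups

    headline: dict = {"group_fractions": fractions}
    # Headline correlations are computed over surface residues only: those
    # with a defined hydration-water order parameter.  Buried or scaffold
    # residues never touch hydration water and carry no zeta.
    surface = table[table["mean_zeta"].notna()]
    pairs = {
        "rmsf_zeta": ("rmsf", "mean_zeta"),
        "sasa_zeta": ("sasa", "mean_zeta"),
        "rmsf_sasa": ("rmsf", "sasa"),
        "tau_zeta_tau_rmsd": ("tau_zeta", "tau_rmsd"),
    }
    for key, (a, b) in pairs.items():
        try:
            headline[f"rho_{key}"] = spearman_rho(surface[a], surface[b])
            slope, _ = linear_fit(surface[a], surface[b])
            headline[f"slope_{key}"] = slope
        except UndefinedCorrelationError:
            headline[f"rho_{key}"] = None
            headline[f"slope_{key}"] = None

    ratio = table["ratio"].dropna()
    headline["ratio_gt1_fraction"] = (
        float((ratio > 1).mean()) if len(ratio) else None
    )

    classed = table[table["class"].isin(CLASS_LABELS)]
    by_class = {}
    for c in CLASS_LABELS:
        sub = classed[classed["class"] == c]
        by_class[c] = {
            q: {
                "mean": float(sub[q].mean()) if sub[q].notna().any() else None,
                "median": float(sub[q].median())
                if sub[q].notna().any() else None,
            }
            for q in ("mean_zeta", "rmsf", "sasa", "tau_zeta", "tau_rmsd",
                      "ratio")
        }
    headline["class_stats"] = by_class
    headline["class_composition"] = {
        g: {
            c: (None if np.isnan(v) else float(v))
            for c, v in row.items()
        }
        for g, row in class_composition(table["group"], table["class"])
        .iterrows()
    }
    return table, headline
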