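"""Physicochemical and elemental contrasts among clades.

The unit of analysis is the unique compound per clade (a compound occurring
in several families of one clade is counted once for that clade; occurrence
weighting is available as an option).  Descriptors: MW (Da) and log10 MW,
XLogP, TPSA (A^2), Fsp3, nitrogen atom count, and the C/O ratio (absent for
oxygen-free compounds).

The hybrid chemical-space coordinates are global Z-scores (sample sd) of
log10 MW and XLogP over the pooled core.  Clade contrasts use tie-corrected
Kruskal-Wallis tests followed by pairwise two-sided Wilcoxon rank-sum tests
with Benjamini-Hochberg correction applied within each descriptor, plus a
compact letter display of the resulting groupings.
"""

from __future__ import annotations

import logging

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import kruskal, mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_DESCRIPTORS",
    "descriptor_table",
    "zscore_space",
    "clade_descriptor_tests",
    "clade_descriptor_summaries",
    "compact_letter_display",
]

logger = logging.getLogger(__name__)

DEFAULT_DESCRIPTORS = ("mw", "fsp3", "xlogp", "tpsa", "n_n", "c_to_o")


def descriptor_table(core, weighted: bool = False) -> pd.DataFrame:
    """Per-compound descriptor table from a chemical core.

    Deduplicated to one row per (inchikey, clade) unless ``weighted``, in
    which case every occurrence row is kept (occurrence-weighted analyses).
    Adds ``log10_mw`` and, if atom counts are present, ``c_to_o``.
    """
    rec = core.records if not hasattr(core, "records") else core.records
    cols = [c for c in ("inchikey", "family", "clade", "mw", "xlogp", "tpsa",
                        "fsp3", "n_c", "n_o", "n_n", "c_to_o") if c in rec.columns]
    df = rec[cols].copy()
    if not weighted:
        df = df.drop_duplicates(["inchikey", "clade"]).reset_index(drop=True)
    if "mw" in df.columns:
        mw = pd.to_numeric(df["mw"], errors="coerce")
        df["log10_mw"] = np.where(mw > 0, np.log10(mw.where(mw > 0)), np.nan)
    if "c_to_o" not in df.columns and {"n_c", "n_o"}.issubset(df.columns):
        n_o = pd.to_numeric(df["n_o"], errors="coerce")
        df["c_to_o"] = np.where(n_o > 0, df["n_c"] / n_o.replace(0, np.nan), np.nan)
    return df


def zscore_space(
    descriptors: pd.DataFrame, columns: tuple[str, str] = ("log10_mw", "xlogp")
) -> pd.DataFrame:
    """Global Z-score coordinates of the hybrid chemical space.

    Standardization uses the pooled mean and sample (n-1) standard
    deviation over non-missing values; missing values stay missing and are
    counted in the ``attrs['n_missing']`` metadata.
    """
    out = descriptors.copy()
    n_missing = {}
    for col in columns:
        x = pd.to_numeric(out[col], errors="coerce")
        n_missing[col] = int(x.isna().sum())
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"degenerate descriptor column {col!r} (sd = 0)")
        out[f"z_{col}"] = (x - x.mean()) / sd
    out.attrs["n_missing"] = n_missing
    return out


def compact_letter_display(
    groups: list[str], significant: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Greedy compact letter display from a pairwise significance matrix.

    Two groups share a letter iff they are NOT significantly different.
    """
    letters: list[set[str]] = []  # each entry: set of groups sharing one letter
    for g in groups:
        placed = False
        for block in letters:
            if all(not significant.get(tuple(sorted((g, h))), False) for h in block):
                block.add(g)
                placed = True
        if not placed:
            letters.append({g})
    # drop blocks fully contained in another (absorption)
    blocks = [b for i, b in enumerate(letters)
              if not any(b < other for j, other in enumerate(letters) if i != j)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    display = {g: "" for g in groups}
    for sym, block in zip(alphabet, blocks):
        for g in sorted(block):
            display[g] += sym
    return display


def clade_descriptor_tests(
    descriptors: pd.DataFrame,
    descriptor_list=DEFAULT_DESCRIPTORS,
    group_col: str = "clade",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis + BH-corrected pairwise rank-sum tests per descriptor.

    The BH family is the set of pairwise comparisons within one descriptor.
    Clades without non-missing values for a descriptor are dropped from
    that descriptor's test with a warning.  Returns one row per descriptor
    with the omnibus H/p, the pairwise table and a compact letter display.
    """
    rows = []
    for desc in descriptor_list:
        if desc not in descriptors.columns:
            continue
        sub = descriptors[[group_col, desc]].dropna()
        samples = {g: s[desc].to_numpy(dtype=float)
                   for g, s in sub.groupby(group_col) if len(s) >= 2}
        dropped = set(descriptors[group_col].unique()) - set(samples)
        if dropped:
            logger.warning("descriptor %s: clades dropped (missing data): %s",
                           desc, sorted(dropped))
        if len(samples) < 2:
            continue
        names = sorted(samples)
        try:
            H, p_kw = kruskal(*[samples[g] for g in names])
        except ValueError:  # all values identical
            H, p_kw = 0.0, 1.0
        pairs = list(combinations(names, 2))
        p_raw = []
        for g1, g2 in pairs:
            try:
                _, p = mannwhitneyu(samples[g1], samples[g2], alternative="two-sided")
            except ValueError:
                p = 1.0
            p_raw.append(p)
        p_adj = multipletests(p_raw, method="fdr_bh")[1] if pairs else np.array([])
        significant = {
            tuple(sorted(pair)): adj < alpha for pair, adj in zip(pairs, p_adj)
        }
        letters = compact_letter_display(names, significant)
        rows.append(
            {
                "descriptor": desc,
                "H": float(H),
                "p_kw": float(p_kw),
                "pairs": [
                    {"clade_a": g1, "clade_b": g2, "p_raw": float(pr), "p_adj": float(pa)}
                    for (g1, g2), pr, pa in zip(pairs, p_raw, p_adj)
                ],
                "letters": letters,
            }
        )
    return pd.DataFrame(rows)


def clade_descriptor_summaries(
    descriptors: pd.DataFrame,
    descriptor_list=DEFAULT_DESCRIPTORS,
    group_col: str = "clade",
) -> pd.DataFrame:
    """Mean +- sample sd per clade per descriptor (missing values excluded)."""
    rows = []
    for desc in descriptor_list:
        if desc not in descriptors.columns:
            continue
        for clade, sub in descriptors.groupby(group_col):
            vals = pd.to_numeric(sub[desc], errors="coerce").dropna()
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "descriptor": desc,
                    "clade": clade,
                    "n": int(len(vals)),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)
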