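"""Allele harmonization between summary-statistic sets.

Two-sample analyses (colocalization, TWAS, MR) require effect sizes from
different studies to refer to the same effect allele.  Variants whose
alleles are swapped between studies have their second-study beta sign
flipped; strand-ambiguous (palindromic A/T, C/G) variants are dropped when
their allele frequency is too close to 0.5 to resolve the strand.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["is_palindromic", "harmonize"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_palindromic(ea: str, oa: str) -> bool:
    """A/T and C/G variants read the same on both strands."""
    return _COMPLEMENT.get(ea.upper()) == oa.upper()


def harmonize(
    left: pd.DataFrame,
    right: pd.DataFrame,
    *,
    ambiguous_eaf_band: tuple[float, float] = (0.4, 0.6),
    on: str = "SNP",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align ``right`` onto ``left``'s effect alleles.

    Both frames carry columns SNP, EA, OA, BETA and optionally EAF.  Rows are
    inner-joined on ``on``; allele-swapped rows get ``right`` BETA negated
    (and EAF mirrored); rows whose alleles match neither orientation are
    dropped; palindromic variants with left EAF inside ``ambiguous_eaf_band``
    are dropped as unresolvable.  Harmonization is idempotent: applying it to
    an already-aligned pair changes nothing.
    """
    lf = left.set_index(on)
    rf = right.set_index(on)
    shared = lf.index.intersection(rf.index)
    lf, rf = lf.loc[shared].copy(), rf.loc[shared].copy()
    lea, loa = lf["EA"].str.upper(), lf["OA"].str.upper()
    rea, roa = rf["EA"].str.upper(), rf["OA"].str.upper()
    same = (lea == rea) & (loa == roa)
    swapped = (lea == roa) & (loa == rea)
    keep = same | swapped
    palin = [is_palindromic(a, b) for a, b in zip(lea, loa)]
    if "EAF" in lf.columns:
        lo, hi = ambiguous_eaf_band
        ambiguous = pd.Series(palin, index=lf.index) & lf["EAF"].between(lo, hi)
        keep &= ~ambiguous
    rf.loc[swapped, "BETA"] = -rf.loc[swapped, "BETA"]
    if "EAF" in rf.columns:
        rf.loc[swapped, "EAF"] = 1.0 - rf.loc[swapped, "EAF"]
    rf.loc[swapped, ["EA", "OA"]] = rf.loc[swapped, ["OA", "EA"]].to_numpy()
    return lf.loc[keep].reset_index(), rf.loc[keep].reset_index()
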