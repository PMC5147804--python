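"""Alignment-level divergence statistics.

Implements the comparative-analysis formulas over annotated pairwise
structural alignments: filtering and tail trimming, percent sequence
identity, class-specific secondary-structure similarity, indel frequency,
similarity-binned aggregation, and per-residue conservation tables.

Secondary-structure similarity for a class X is the number of aligned
(non-gap) columns with X on both sides divided by the number of aligned
columns with X on at least one side; indel frequency for X is the number
of gap-opposed X residues divided by all X residues appearing in the
alignment (both sides counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .structcalc import ResidueAnnotation
from .structio import GAP, EmptyAlignmentError, PairAlignment

__all__ = [
    "AnnotatedAlignment",
    "AlignmentMetrics",
    "FilterResult",
    "filter_alignment",
    "trim_tails",
    "seq_similarity",
    "ss_similarity",
    "indel_frequency",
    "alignment_metrics",
    "bin_alignments",
    "per_residue_conservation",
    "DEFAULT_EXCLUDED_FAMILIES",
]

#: Antibody variable and constant domain families, excluded by default.
DEFAULT_EXCLUDED_FAMILIES = frozenset({"b.1.1.1", "b.1.1.2"})

SS_CLASSES = ("H", "E", "C")


@dataclass
class AnnotatedAlignment:
    """A pairwise alignment plus per-residue annotations on both sides."""

    pa: PairAlignment
    ann1: Sequence[ResidueAnnotation]
    ann2: Sequence[ResidueAnnotation]

    def __post_init__(self):
        for c1, c2 in self.pa.columns:
            if c1 is not GAP and c1 >= len(self.ann1):
                raise ValueError("side-1 column index without annotation")
            if c2 is not GAP and c2 >= len(self.ann2):
                raise ValueError("side-2 column index without annotation")

    def swapped(self) -> "AnnotatedAlignment":
        pa = PairAlignment(self.pa.id2, self.pa.id1, self.pa.tm_score,
                           [(c2, c1) for c1, c2 in self.pa.columns],
                           seq1=self.pa.seq2, seq2=self.pa.seq1,
                           family1=self.pa.family2, family2=self.pa.family1)
        return AnnotatedAlignment(pa, self.ann2, self.ann1)


@dataclass
class AlignmentMetrics:
    id1: str
    id2: str
    n_columns: int
    seq_similarity: float                      # percent, [0, 100]
    ss_similarity: dict[str, Optional[float]]  # per class + 'any', fraction
    indel_frequency: dict[str, Optional[float]]

    def as_row(self) -> dict:
        row = {"id1": self.id1, "id2": self.id2, "n_columns": self.n_columns,
               "seq_similarity": self.seq_similarity}
        for cls, v in self.ss_similarity.items():
            row[f"ss_sim_{cls}"] = v
        for cls, v in self.indel_frequency.items():
            row[f"indel_{cls}"] = v
        return row


@dataclass(frozen=True)
class FilterResult:
    keep: bool
    reason: Optional[str] = None   # 'tm', 'length', 'family', 'numbering'


def filter_alignment(
    pa: PairAlignment,
    tm_min: float = 0.5,
    min_len: int = 80,
    excluded_families: frozenset = DEFAULT_EXCLUDED_FAMILIES,
    len1: Optional[int] = None,
    len2: Optional[int] = None,
    monotonic1: bool = True,
    monotonic2: bool = True,
) -> FilterResult:
    """Apply the standard alignment exclusion rules.

    Rejects alignments with TM-score below ``tm_min``, either domain
    shorter than ``min_len`` residues, either family in the exclusion set,
    or either domain with non-monotonic residue numbering.
    """
    if pa.tm_score < tm_min:
        return FilterResult(False, "tm")
    l1 = len(pa.seq1) if len1 is None else len1
    l2 = len(pa.seq2) if len2 is None else len2
    if l1 < min_len or l2 < min_len:
        return FilterResult(False, "length")
    if pa.family1 in excluded_families or pa.family2 in excluded_families:
        return FilterResult(False, "family")
    if not (monotonic1 and monotonic2):
        return FilterResult(False, "numbering")
    return FilterResult(True)


def trim_tails(pa: PairAlignment) -> PairAlignment:
    """Remove leading and trailing runs of gap-containing columns."""
    cols = pa.columns
    lo = 0
    while lo < len(cols) and (cols[lo][0] is GAP or cols[lo][1] is GAP):
        lo += 1
    hi = len(cols)
    while hi > lo and (cols[hi - 1][0] is GAP or cols[hi - 1][1] is GAP):
        hi -= 1
    if hi <= lo:
        raise EmptyAlignmentError(
            f"alignment {pa.id1}/{pa.id2} is all gap-containing columns")
    return PairAlignment(pa.id1, pa.id2, pa.tm_score, list(cols[lo:hi]),
                         seq1=pa.seq1, seq2=pa.seq2,
                         family1=pa.family1, family2=pa.family2)


def seq_similarity(pa: PairAlignment,
                   seq1: Optional[str] = None,
                   seq2: Optional[str] = None) -> float:
    """Percent identity over aligned (non-gap) columns."""
    s1 = seq1 if seq1 is not None else pa.seq1
    s2 = seq2 if seq2 is not None else pa.seq2
    ident = total = 0
    for c1, c2 in pa.columns:
        if c1 is GAP or c2 is GAP:
            continue
        total += 1
        if s1[c1] == s2[c2]:
            ident += 1
    if total == 0:
        raise EmptyAlignmentError("no aligned columns to compare")
    return 100.0 * ident / total


def ss_similarity(aa: AnnotatedAlignment, cls: str = "any",
                  rsa_range: Optional[tuple[float, float]] = None,
                  ) -> Optional[float]:
    """Class-specific secondary-structure similarity.

    For a class in H/E/C: columns with the class on both sides over columns
    with the class on at least one side.  For 'any': columns with equal ss3
    over all aligned columns.  ``rsa_range`` restricts the accounting to
    columns whose side-1 (reference) RSA lies in the half-open interval
    [lo, hi); the top interval is closed above implicitly because RSA > 1
    is retained.  Returns None when the denominator is empty.
    """
    num = den = 0
    for c1, c2 in aa.pa.columns:
        if c1 is GAP or c2 is GAP:
            continue
        if rsa_range is not None:
            r = aa.ann1[c1].rsa
            if r is None:
                continue
            lo, hi = rsa_range
            in_top = hi >= 1.0 and r >= lo      # open-ended top bin
            if not (lo <= r < hi or in_top):
                continue
        s1, s2 = aa.ann1[c1].ss3, aa.ann2[c2].ss3
        if cls == "any":
            den += 1
            num += s1 == s2
        else:
            if s1 == cls or s2 == cls:
                den += 1
                num += s1 == cls and s2 == cls
    if den == 0:
        return None
    return num / den


def indel_frequency(aa: AnnotatedAlignment, cls: str) -> Optional[float]:
    """Fraction of class-``cls`` residues in the alignment opposite a gap.

    Counts residues on both sides: the denominator is every residue of the
    class appearing in any column, the numerator those in gap-opposed
    columns.  Returns None when no residue of the class appears.
    """
    num = den = 0
    for c1, c2 in aa.pa.columns:
        if c1 is not GAP and aa.ann1[c1].ss3 == cls:
            den += 1
            num += c2 is GAP
        if c2 is not GAP and aa.ann2[c2].ss3 == cls:
            den += 1
            num += c1 is GAP
    if den == 0:
        return None
    return num / den


def alignment_metrics(aa: AnnotatedAlignment) -> AlignmentMetrics:
    """All per-alignment statistics in one record (alignment pre-trimmed)."""
    return AlignmentMetrics(
        id1=aa.pa.id1,
        id2=aa.pa.id2,
        n_columns=aa.pa.n_columns,
        seq_similarity=seq_similarity(aa.pa),
        ss_similarity={cls: ss_similarity(aa, cls) for cls in (*SS_CLASSES, "any")},
        indel_frequency={cls: indel_frequency(aa, cls) for cls in SS_CLASSES},
    )


def bin_alignments(rows: Iterable[AlignmentMetrics] | pd.DataFrame,
                   bin_width: float = 10.0,
                   value_columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Group alignments into sequence-similarity bins and aggregate.

    Bins are half-open [lo, lo+w) with the last bin closed at 100.  For
    every value column the per-bin mean, normal-approximation 95% CI and n
    are reported; empty bins appear with n = 0.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame([m.as_row() for m in rows])
    if value_columns is None:
        value_columns = [c for c in rows.columns if c.startswith(("ss_sim_", "indel_"))]

    edges = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
    if edges[-1] < 100.0:
        edges = np.append(edges, 100.0)
    # np.digitize with right=False gives half-open bins; fold 100 into last
    idx = np.digitize(rows["seq_similarity"], edges[1:-1], right=False)

    out = []
    for b in range(len(edges) - 1):
        sub = rows[idx == b]
        rec = {"bin_lo": edges[b], "bin_hi": edges[b + 1],
               "bin_label": f"{edges[b]:g}-{edges[b + 1]:g}%", "n": len(sub)}
        for col in value_columns:
            vals = sub[col].dropna() if len(sub) else pd.Series(dtype=float)
            if len(vals):
                mean = float(vals.mean())
                se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
                rec[f"{col}_mean"] = mean
                rec[f"{col}_ci_lo"] = mean - 1.959963984540054 * se
                rec[f"{col}_ci_hi"] = mean + 1.959963984540054 * se
                rec[f"{col}_n"] = len(vals)
            else:
                rec[f"{col}_mean"] = np.nan
                rec[f"{col}_ci_lo"] = np.nan
                rec[f"{col}_ci_hi"] = np.nan
                rec[f"{col}_n"] = 0
        out.append(rec)
    return pd.DataFrame(out)


def per_residue_conservation(
    alignments: Iterable[AnnotatedAlignment],
    group_by: Sequence[str] = ("ss3",),
    rsa_bin_width: float = 0.1,
    sequences: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """P(secondary structure retained) per residue group.

    Walks every aligned column of every alignment (side-1 perspective) and
    groups residues by any subset of {'aa', 'ss3', 'rsa_bin'}; 'aa'
    requires the side-1 sequence, taken from the alignment record or the
    ``sequences`` mapping.  Reports retained / total counts and the
    fraction, which feeds the proportion tests.
    """
    valid = {"aa", "ss3", "rsa_bin"}
    if not set(group_by) <= valid:
        raise ValueError(f"group_by must be a subset of {valid}")
    counts: dict[tuple, list[int]] = {}
    for aa_aln in alignments:
        seq1 = aa_aln.pa.seq1 or (sequences or {}).get(aa_aln.pa.id1, "")
        for c1, c2 in aa_aln.pa.columns:
            if c1 is GAP or c2 is GAP:
                continue
            a1, a2 = aa_aln.ann1[c1], aa_aln.ann2[c2]
            key = []
            if "aa" in group_by:
                if not seq1:
                    raise ValueError("'aa' grouping needs side-1 sequences")
                key.append(seq1[c1])
            if "ss3" in group_by:
                key.append(a1.ss3)
            if "rsa_bin" in group_by:
                if a1.rsa is None:
                    continue
                b = min(int(a1.rsa / rsa_bin_width), int(round(1.0 / rsa_bin_width)) - 1)
                key.append(f"[{b * rsa_bin_width:g},{(b + 1) * rsa_bin_width:g})")
            cell = counts.setdefault(tuple(key), [0, 0])
            cell[1] += 1
            cell[0] += a1.ss3 == a2.ss3
    rows = []
    for key, (kept, total) in sorted(counts.items()):
        rows.append({**{g: k for g, k in zip(group_by, key)},
                     "retained": kept, "n": total, "fraction": kept / total})
    return pd.DataFrame(rows)
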