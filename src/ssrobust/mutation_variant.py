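"""Point-mutant discovery between near-identical structures and
missense-variant stratification.

The discovery procedure mirrors a redundancy-aware scan of a structure
database: exact-duplicate sequences are collapsed, near-identical pairs
(>= 98% identity over aligned columns, both sequences >= 64 residues) are
found with a k-mer prefilter plus global alignment, substitutions are
called with a minimum mutual spacing of 10 residues, and equivalent
mutations within a homology group are counted once.

Variant-side analyses stratify human missense variants by RSA bin,
secondary-structure-change status and PolyPhen-2 score bin, with Wilson
confidence intervals, Benjamini-Hochberg-corrected proportion tests and
rank-sum comparisons of folding-free-energy changes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from Bio import Align

from .stats import benjamini_hochberg, prop_test, wilson_ci

__all__ = [
    "MutationPair",
    "SSUnit",
    "segment_ss_units",
    "dedupe_sequences",
    "find_similar_pairs",
    "align_pair",
    "call_mutations",
    "dedupe_mutations",
    "classify_ss_change",
    "distance_to_unit_end",
    "map_variant_rsa",
    "consensus_ss_prediction",
    "pathogenic_fraction_table",
    "ddg_compare",
    "scan_mutants",
    "PP2_BIN_EDGES",
    "pp2_bin_label",
    "rsa_bin_label",
    "read_variant_table",
    "VARIANT_REQUIRED_COLUMNS",
]

#: PolyPhen-2 category edges: benign, possibly, probably, highly likely damaging
PP2_BIN_EDGES = (0.0, 0.49, 0.89, 0.99, 1.0)
PP2_BIN_LABELS = ("0-0.49", "0.5-0.89", "0.9-0.99", "0.99-1")

VARIANT_REQUIRED_COLUMNS = ("protein_id", "position", "wt_aa", "mut_aa",
                            "label", "pp2", "rsa")


@dataclass
class MutationPair:
    """One amino-acid substitution between two near-identical structures."""

    id1: str
    id2: str
    pos1: int                 # 0-based position in sequence 1
    pos2: int                 # 0-based position in sequence 2
    wt_aa: str
    mut_aa: str
    rsa: Optional[float] = None          # RSA of the wild-type residue
    ss3_wt: Optional[str] = None
    ss3_mut: Optional[str] = None
    unit_end_distance: Optional[int] = None

    def __post_init__(self):
        if self.wt_aa == self.mut_aa:
            raise ValueError("wt and mut amino acids must differ")
        if self.rsa is not None and self.rsa < 0:
            raise ValueError("rsa must be >= 0")

    @property
    def changed(self) -> Optional[bool]:
        if self.ss3_wt is None or self.ss3_mut is None:
            return None
        return self.ss3_wt != self.ss3_mut


@dataclass(frozen=True)
class SSUnit:
    ss3: str
    start: int   # inclusive
    end: int     # inclusive


def segment_ss_units(ss3: Sequence[str]) -> list[SSUnit]:
    """Maximal runs of identical 3-state secondary structure."""
    units = []
    start = 0
    for i in range(1, len(ss3) + 1):
        if i == len(ss3) or ss3[i] != ss3[start]:
            units.append(SSUnit(ss3[start], start, i - 1))
            start = i
    return units


def distance_to_unit_end(index: int, units: Sequence[SSUnit]) -> Optional[int]:
    """Distance (residues) to the nearest end of the residue's H/E unit.

    0 at either terminus of the unit; None for coil residues (no unit).
    """
    for u in units:
        if u.start <= index <= u.end:
            if u.ss3 == "C":
                return None
            return min(index - u.start, u.end - index)
    raise IndexError(f"residue {index} not covered by the segmentation")


# ---------------------------------------------------------------------------
# Sequence-pair discovery

def dedupe_sequences(seqs: dict[str, str]) -> dict[str, str]:
    """Collapse exact duplicate sequences (uppercase-canonical), keep first id."""
    seen: dict[str, str] = {}
    out: dict[str, str] = {}
    for sid, seq in seqs.items():
        canon = seq.upper()
        if canon not in seen:
            seen[canon] = sid
            out[sid] = canon
    return out


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def align_pair(seq1: str, seq2: str):
    """Global alignment -> (identity fraction, columns).

    Columns are (i | None, j | None) index pairs; identity is identical
    columns over aligned (non-gap) columns.
    """
    aln = _make_aligner().align(seq1, seq2)[0]
    cols: list[tuple[Optional[int], Optional[int]]] = []
    (b1, b2) = aln.aligned
    prev1 = prev2 = 0
    for (s1, e1), (s2, e2) in zip(b1, b2):
        for i in range(prev1, s1):
            cols.append((i, None))
        for j in range(prev2, s2):
            cols.append((None, j))
        for k in range(e1 - s1):
            cols.append((s1 + k, s2 + k))
        prev1, prev2 = e1, e2
    for i in range(prev1, len(seq1)):
        cols.append((i, None))
    for j in range(prev2, len(seq2)):
        cols.append((None, j))

    ident = aligned = 0
    for c1, c2 in cols:
        if c1 is not None and c2 is not None:
            aligned += 1
            ident += seq1[c1] == seq2[c2]
    identity = ident / aligned if aligned else 0.0
    return identity, cols


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def find_similar_pairs(seqs: dict[str, str], min_id: float = 0.98,
                       min_len: int = 64, k: int = 8,
                       ) -> list[tuple[str, str, float]]:
    """Near-identical sequence pairs (id1 < id2 lexicographically ordered ids
    as given), via shared-k-mer prefilter then global alignment.

    For substitution-only pairs at >= min_id over >= min_len residues the
    prefilter is lossless by pigeonhole: the longest exact run between the
    sequences is at least (L - d) / (d + 1) >= k.
    """
    ids = [sid for sid, s in seqs.items() if len(s) >= min_len]
    kmers = {sid: _kmer_set(seqs[sid], k) for sid in ids}
    out = []
    for a, b in itertools.combinations(ids, 2):
        if not (kmers[a] & kmers[b]):
            continue
        identity, _ = align_pair(seqs[a], seqs[b])
        if identity >= min_id and identity < 1.0:
            out.append((a, b, identity))
    return out


def call_mutations(id1: str, id2: str, seq1: str, seq2: str,
                   columns: Optional[list] = None,
                   min_spacing: int = 10) -> list[MutationPair]:
    """Substitutions between an aligned near-identical pair.

    Columns adjacent to indels are skipped.  When more than one
    substitution is present, only those whose nearest other substitution
    lies at least ``min_spacing`` residues away (sequence-1 coordinates)
    are retained.
    """
    if columns is None:
        _, columns = align_pair(seq1, seq2)
    subs = []
    for ci, (c1, c2) in enumerate(columns):
        if c1 is None or c2 is None or seq1[c1] == seq2[c2]:
            continue
        neighbor_gap = any(
            0 <= ci + d < len(columns)
            and (columns[ci + d][0] is None or columns[ci + d][1] is None)
            for d in (-1, 1))
        if neighbor_gap:
            continue
        subs.append((c1, c2))
    if len(subs) > 1:
        kept = []
        for i, (c1, c2) in enumerate(subs):
            nearest = min(abs(c1 - other[0]) for j, other in enumerate(subs) if j != i)
            if nearest >= min_spacing:
                kept.append((c1, c2))
        subs = kept
    return [MutationPair(id1, id2, c1, c2, seq1[c1], seq2[c2]) for c1, c2 in subs]


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def dedupe_mutations(mutations: Iterable[MutationPair],
                     pairs: Iterable[tuple[str, str]],
                     seqs: dict[str, str]) -> list[MutationPair]:
    """One record per distinct mutation within each homology group.

    Homology groups are connected components of the similarity-pair graph;
    equivalent positions across homologs are resolved by aligning each
    member to its group representative (smallest id) and mapping through
    the alignment columns.  Output order is deterministic (sorted by key)
    and invariant to input order.
    """
    uf = _UnionFind()
    for a, b in pairs:
        uf.union(a, b)

    posmap_cache: dict[str, dict[int, int]] = {}

    def to_rep(sid: str, pos: int):
        rep = uf.find(sid)
        if rep == sid:
            return pos
        if sid not in posmap_cache:
            _, cols = align_pair(seqs[sid], seqs[rep])
            posmap_cache[sid] = {c1: c2 for c1, c2 in cols
                                 if c1 is not None and c2 is not None}
        return posmap_cache[sid].get(pos, f"unmapped:{sid}:{pos}")

    best: dict[tuple, MutationPair] = {}
    for mp in mutations:
        key = (uf.find(mp.id1), to_rep(mp.id1, mp.pos1), mp.wt_aa, mp.mut_aa)
        if key not in best or (mp.id1, mp.id2, mp.pos1) < (
                best[key].id1, best[key].id2, best[key].pos1):
            best[key] = mp
    return [best[k] for k in sorted(best, key=str)]


def scan_mutants(seqs: dict[str, str], min_id: float = 0.98, min_len: int = 64,
                 min_spacing: int = 10) -> list[MutationPair]:
    """Full discovery pipeline: dedupe, pair, call, collapse redundancies."""
    unique = dedupe_sequences(seqs)
    pairs = find_similar_pairs(unique, min_id=min_id, min_len=min_len)
    muts: list[MutationPair] = []
    for a, b, _ in pairs:
        muts.extend(call_mutations(a, b, unique[a], unique[b],
                                   min_spacing=min_spacing))
    return dedupe_mutations(muts, [(a, b) for a, b, _ in pairs], unique)


# ---------------------------------------------------------------------------
# Structural classification of mutations

def classify_ss_change(mp: MutationPair, ann1, ann2) -> Optional[MutationPair]:
    """Fill ss3/RSA fields from per-residue annotations of both structures.

    RSA is taken from the wild-type (side-1) structure.  Returns None when
    either annotation is missing at the mutated residue (record excluded).
    """
    if mp.pos1 >= len(ann1) or mp.pos2 >= len(ann2):
        return None
    a1, a2 = ann1[mp.pos1], ann2[mp.pos2]
    if a1 is None or a2 is None:
        return None
    mp.ss3_wt = a1.ss3
    mp.ss3_mut = a2.ss3
    mp.rsa = a1.rsa
    units = segment_ss_units([a.ss3 for a in ann1])
    mp.unit_end_distance = distance_to_unit_end(mp.pos1, units)
    return mp


def map_variant_rsa(rsa_candidates: Sequence[float]) -> Optional[float]:
    """Lowest RSA across all structures a variant maps to; None when unmapped."""
    vals = [r for r in rsa_candidates if r is not None]
    if not vals:
        return None
    return float(min(vals))


def consensus_ss_prediction(pred1: tuple[str, str], pred2: tuple[str, str],
                            observed_wt: str) -> tuple[bool, Optional[bool]]:
    """(usable, predicted change) from two independent SS predictors.

    Each prediction is a (wt ss3, mut ss3) pair.  The record is usable only
    when both predictors reproduce the observed wild-type state and agree
    on the mutant state; the predicted change is then consensus-mutant !=
    wild type.
    """
    wt1, mut1 = pred1
    wt2, mut2 = pred2
    if wt1 != observed_wt or wt2 != observed_wt or mut1 != mut2:
        return False, None
    return True, mut1 != observed_wt


# ---------------------------------------------------------------------------
# Variant tables

def pp2_bin_label(pp2: float) -> str:
    """PolyPhen-2 category: [0,0.49], (0.49,0.89], (0.89,0.99], (0.99,1]."""
    if not (0.0 <= pp2 <= 1.0):
        raise ValueError(f"pp2 score {pp2} outside [0,1]")
    for lo, hi, lab in zip(PP2_BIN_EDGES[:-1], PP2_BIN_EDGES[1:], PP2_BIN_LABELS):
        if pp2 <= hi:
            return lab
    return PP2_BIN_LABELS[-1]


def rsa_bin_label(rsa: float, width: float = 0.2) -> str:
    """Half-open RSA bin label; values >= 1 fall in the top bin."""
    n_bins = int(round(1.0 / width))
    b = min(int(rsa / width), n_bins - 1)
    return f"[{b * width:g},{(b + 1) * width:g})"


def read_variant_table(path) -> pd.DataFrame:
    """Read a variant TSV and validate the schema."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VARIANT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing required columns: {missing}")
    bad = df[(df["pp2"] < 0) | (df["pp2"] > 1)]
    if len(bad):
        raise ValueError(f"{len(bad)} variant(s) with pp2 outside [0,1]")
    if not set(df["label"]) <= {"pathogenic", "neutral"}:
        raise ValueError("label must be 'pathogenic' or 'neutral'")
    return df


def pathogenic_fraction_table(variants: pd.DataFrame,
                              by: Sequence[str] = ("rsa_bin",),
                              rsa_bin_width: float = 0.2) -> pd.DataFrame:
    """Pathogenic fraction per stratum with Wilson CIs and corrected tests.

    Strata are the cartesian product of ``by`` (subset of {'rsa_bin',
    'pp2_bin'}) with the secondary-structure-change flag; within every
    stratum cell the change/no-change proportions are compared with a
    two-proportion test and the p-values are Benjamini-Hochberg corrected
    across cells.  Requires columns label, ss_change and rsa and/or pp2.
    """
    df = variants.copy()
    if "rsa_bin" in by:
        df["rsa_bin"] = df["rsa"].apply(lambda r: rsa_bin_label(r, rsa_bin_width))
    if "pp2_bin" in by:
        df["pp2_bin"] = df["pp2"].apply(pp2_bin_label)
    df["pathogenic"] = (df["label"] == "pathogenic").astype(int)

    rows = []
    for key, sub in df.groupby([*by, "ss_change"], sort=True):
        k = int(sub["pathogenic"].sum())
        n = len(sub)
        lo, hi = wilson_ci(k, n) if n else (np.nan, np.nan)
        rec = dict(zip([*by, "ss_change"], key if isinstance(key, tuple) else (key,)))
        rec.update(n=n, n_pathogenic=k, fraction=k / n if n else np.nan,
                   ci_lo=lo, ci_hi=hi)
        rows.append(rec)
    table = pd.DataFrame(rows)

    tests = []
    for key, cell in table.groupby(list(by), sort=True):
        flags = dict(zip(cell["ss_change"], cell.index))
        if True in flags and False in flags:
            a, b = table.loc[flags[True]], table.loc[flags[False]]
            res = prop_test(int(a["n_pathogenic"]), int(a["n"]),
                            int(b["n_pathogenic"]), int(b["n"]))
            rec = dict(zip(by, key if isinstance(key, tuple) else (key,)))
            rec.update(frac_change=res.p1, frac_nochange=res.p2,
                       p_value=res.p_value, method=res.method)
            tests.append(rec)
    tests = pd.DataFrame(tests)
    if len(tests):
        tests["p_adj_bh"] = benjamini_hochberg(tests["p_value"].to_numpy())
    table.attrs["tests"] = tests
    return table


def ddg_compare(variants: pd.DataFrame, group_col: str = "ss_change",
                rsa_bin_width: float = 0.2) -> pd.DataFrame:
    """Per-RSA-bin folding-stability (ddG) comparison between two groups.

    ``group_col`` may be 'ss_change', 'label' or 'ss3'.  Reports per-group
    mean/median ddG and a two-sided rank-sum test per bin, BH-corrected
    across bins; strata with fewer than 2 observations skip the test.
    """
    if "ddg" not in variants.columns:
        raise ValueError("ddg column required")
    df = variants.dropna(subset=["ddg"]).copy()
    df["rsa_bin"] = df["rsa"].apply(lambda r: rsa_bin_label(r, rsa_bin_width))

    rows = []
    for rbin, sub in df.groupby("rsa_bin", sort=True):
        levels = sorted(sub[group_col].unique(), key=str)
        rec = {"rsa_bin": rbin}
        for lv in levels:
            vals = sub.loc[sub[group_col] == lv, "ddg"]
            rec[f"mean_{lv}"] = float(vals.mean())
            rec[f"median_{lv}"] = float(vals.median())
            rec[f"n_{lv}"] = len(vals)
        if len(levels) == 2:
            g1 = sub.loc[sub[group_col] == levels[0], "ddg"]
            g2 = sub.loc[sub[group_col] == levels[1], "ddg"]
            if len(g1) >= 2 and len(g2) >= 2:
                stat, p = scipy.stats.mannwhitneyu(g1, g2, alternative="two-sided")
                rec["p_value"] = float(p)
                rec["skipped"] = False
            else:
                rec["p_value"] = np.nan
                rec["skipped"] = True
        rows.append(rec)
    out = pd.DataFrame(rows)
    if "p_value" in out.columns:
        mask = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = benjamini_hochberg(out.loc[mask, "p_value"].to_numpy())
        out["p_adj_bh"] = adj
    return out
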