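"""End-to-end report runs over annotated alignments and variant tables.

``run_comparative`` takes a set of annotated pairwise alignments (parsed
from files or generated synthetically), applies the exclusion rules,
computes per-pair metrics, similarity-binned summaries, the
contact-regression residue subsetting rerun, within-class divergence
tables, per-amino-acid conservation and contact-distance tables, and the
associated proportion tests with multiple-testing correction.

``run_variant_analysis`` takes a variant table and emits the pathogenic
fraction stratifications (by RSA bin and by PolyPhen-2 bin), the
per-class break-frequency table, and the ddG comparisons.

Every input record is accounted for: kept plus excluded-by-reason counts
sum to the input count, and the exclusion log is part of the bundle.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import align_metrics as am
from . import mutation_variant as mv
from . import stats as st
from .align_metrics import AnnotatedAlignment

logger = logging.getLogger("ssrobust")

__all__ = ["RunConfig", "EmptyResultError", "run_comparative",
           "run_variant_analysis", "write_bundle"]


class EmptyResultError(RuntimeError):
    """No records survived filtering."""


@dataclass
class RunConfig:
    """Thresholds and binning for a pipeline run."""

    tm_min: float = 0.5
    min_len: int = 80
    min_id: float = 0.98
    min_spacing: int = 10
    bin_width: float = 10.0
    sim_window: tuple[float, float] = (10.0, 20.0)
    ancova_window: tuple[float, float] = (10.0, 30.0)
    rsa_bin_width_alignment: float = 0.1
    rsa_bin_width_variant: float = 0.2
    mcd_bin_edges: tuple = (1, 5, 10, 20, 40, 1000)
    alpha: float = 0.05
    seed: int = 0
    outdir: Optional[str] = None

    def validate(self) -> None:
        if not (0 <= self.tm_min <= 1.01):
            raise ValueError("tm_min out of range")
        if self.min_len < 1 or self.min_spacing < 0:
            raise ValueError("invalid length/spacing thresholds")
        if not (0 < self.bin_width <= 100):
            raise ValueError("bin_width out of range")


def _in_window(x: float, window: tuple[float, float]) -> bool:
    return window[0] <= x < window[1]


def _class_seq_similarity(aln: AnnotatedAlignment, cls: str) -> Optional[float]:
    """Percent identity over columns with class ``cls`` on both sides."""
    ident = total = 0
    for c1, c2 in aln.pa.columns:
        if c1 is None or c2 is None:
            continue
        if aln.ann1[c1].ss3 == cls and aln.ann2[c2].ss3 == cls:
            total += 1
            ident += aln.pa.seq1[c1] == aln.pa.seq2[c2]
    return 100.0 * ident / total if total else None


def _residue_frame(alignments: Sequence[AnnotatedAlignment]) -> pd.DataFrame:
    """One row per aligned column (side-1 perspective)."""
    rows = []
    for k, aln in enumerate(alignments):
        for c1, c2 in aln.pa.columns:
            if c1 is None or c2 is None:
                continue
            a1, a2 = aln.ann1[c1], aln.ann2[c2]
            rows.append({
                "alignment": k, "pos": c1, "ss3": a1.ss3, "rsa": a1.rsa,
                "n_contacts": a1.n_contacts,
                "mean_contact_distance": a1.mean_contact_distance,
                "retained": a1.ss3 == a2.ss3,
                "aa": aln.pa.seq1[c1] if aln.pa.seq1 else None,
            })
    return pd.DataFrame(rows)


def _conservation_by_class(res: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Per-class retention with Wilson CI and H-vs-E proportion test."""
    rows = []
    for cls, sub in res.groupby("ss3"):
        k, n = int(sub["retained"].sum()), len(sub)
        lo, hi = st.wilson_ci(k, n)
        rows.append({"ss3": cls, "retained": k, "n": n,
                     "fraction": k / n, "ci_lo": lo, "ci_hi": hi})
    out = pd.DataFrame(rows).sort_values("ss3").reset_index(drop=True)
    h = out[out["ss3"] == "H"]
    e = out[out["ss3"] == "E"]
    if len(h) and len(e):
        res_t = st.prop_test(int(h["retained"].iloc[0]), int(h["n"].iloc[0]),
                             int(e["retained"].iloc[0]), int(e["n"].iloc[0]),
                             alpha=alpha)
        out.attrs["h_vs_e"] = {"p_value": res_t.p_value, "method": res_t.method,
                               "diff": res_t.p1 - res_t.p2}
    return out


def run_comparative(
    alignments: Iterable[tuple[AnnotatedAlignment, dict]] | Iterable[AnnotatedAlignment],
    config: Optional[RunConfig] = None,
) -> dict:
    """Comparative-analysis report bundle from annotated alignments.

    ``alignments`` may carry per-alignment metadata dicts (length and
    monotonicity per side, family labels) used by the exclusion rules;
    bare AnnotatedAlignment objects are accepted and default to passing
    metadata.  Raises :class:`EmptyResultError` when nothing survives.
    """
    config = config or RunConfig()
    config.validate()

    exclusions: Counter = Counter()
    kept: list[AnnotatedAlignment] = []
    n_input = 0
    for item in alignments:
        aln, meta = item if isinstance(item, tuple) else (item, {})
        n_input += 1
        fr = am.filter_alignment(
            aln.pa, tm_min=config.tm_min, min_len=config.min_len,
            len1=meta.get("len1"), len2=meta.get("len2"),
            monotonic1=meta.get("monotonic1", True),
            monotonic2=meta.get("monotonic2", True))
        if not fr.keep:
            exclusions[fr.reason] += 1
            continue
        try:
            trimmed = am.trim_tails(aln.pa)
        except Exception:
            exclusions["all_gap"] += 1
            continue
        kept.append(AnnotatedAlignment(trimmed, aln.ann1, aln.ann2))
    for reason, cnt in sorted(exclusions.items()):
        logger.info("excluded %d alignment(s): %s", cnt, reason)
    assert len(kept) + sum(exclusions.values()) == n_input
    if not kept:
        raise EmptyResultError("no alignments survived filtering")

    metrics = [am.alignment_metrics(a) for a in kept]
    per_pair = pd.DataFrame([m.as_row() for m in metrics])
    binned = am.bin_alignments(metrics, bin_width=config.bin_width)

    # per-RSA-bin class similarity in the dense similarity window
    window_alns = [a for a, m in zip(kept, metrics)
                   if _in_window(m.seq_similarity, config.sim_window)]
    w = config.rsa_bin_width_alignment
    rsa_rows = []
    for b in range(int(round(1.0 / w))):
        rng_ = (b * w, (b + 1) * w)
        for cls in "HEC":
            vals = [v for v in (am.ss_similarity(a, cls, rsa_range=rng_)
                                for a in window_alns) if v is not None]
            rsa_rows.append({
                "rsa_bin": f"[{rng_[0]:g},{rng_[1]:g})", "ss3": cls,
                "mean_ss_similarity": float(np.mean(vals)) if vals else np.nan,
                "n_alignments": len(vals)})
    rsa_binned = pd.DataFrame(rsa_rows)

    res = _residue_frame(window_alns)
    if len(res):
        res_valid = res.dropna(subset=["rsa"])
        conservation_all = _conservation_by_class(res_valid, config.alpha)
        try:
            subset = st.subset_by_contact_regression(res_valid)
            conservation_subset = _conservation_by_class(subset, config.alpha)
        except ValueError:
            subset = pd.DataFrame()
            conservation_subset = pd.DataFrame()
        per_aa = am.per_residue_conservation(
            window_alns, group_by=("aa", "ss3"),
            rsa_bin_width=config.rsa_bin_width_alignment)
        mcd = res_valid.dropna(subset=["mean_contact_distance"]).copy()
        edges = config.mcd_bin_edges
        mcd["mcd_bin"] = pd.cut(mcd["mean_contact_distance"], bins=list(edges),
                                right=False)
        mcd_rows = []
        for (b, cls), sub in mcd.groupby(["mcd_bin", "ss3"], observed=True):
            if not len(sub):
                continue
            k, n = int(sub["retained"].sum()), len(sub)
            lo, hi = st.wilson_ci(k, n)
            mcd_rows.append({"mcd_bin": str(b), "ss3": cls, "retained": k,
                             "n": n, "fraction": k / n, "ci_lo": lo, "ci_hi": hi})
        contact_distance = pd.DataFrame(mcd_rows)
    else:
        conservation_all = conservation_subset = pd.DataFrame()
        per_aa = contact_distance = pd.DataFrame()

    # within-domain divergence by class (per-class identity vs global)
    div_rows = []
    for aln_, m in zip(kept, metrics):
        row = {"id1": m.id1, "id2": m.id2, "seq_similarity": m.seq_similarity}
        for cls in "HEC":
            row[f"seq_sim_{cls}"] = _class_seq_similarity(aln_, cls)
        div_rows.append(row)
    divergence = pd.DataFrame(div_rows)

    # ANCOVA of class retention vs RSA in the wider window
    anc_alns = [a for a, m in zip(kept, metrics)
                if _in_window(m.seq_similarity, config.ancova_window)]
    anc = None
    res_anc = _residue_frame(anc_alns)
    if len(res_anc):
        he = res_anc[res_anc["ss3"].isin(["H", "E"])].dropna(subset=["rsa"])
        if he["ss3"].nunique() == 2 and len(he) > 10:
            try:
                anc_res = st.ancova(he["retained"].astype(float).to_numpy(),
                                    he["ss3"].to_numpy(), he["rsa"].to_numpy())
                anc = {"f": anc_res.f_statistic, "p": anc_res.p_value,
                       "slope": anc_res.covariate_slope,
                       "adjusted_means": anc_res.adjusted_group_means,
                       "n": len(he)}
            except st.SingularDesignError:
                anc = None

    return {
        "per_pair": per_pair,
        "binned": binned,
        "rsa_binned": rsa_binned,
        "conservation_all": conservation_all,
        "conservation_contact_subset": conservation_subset,
        "divergence_by_class": divergence,
        "per_amino_acid": per_aa,
        "contact_distance": contact_distance,
        "ancova_h_vs_e": anc,
        "exclusions": dict(exclusions),
        "n_input": n_input,
        "n_kept": len(kept),
    }


def run_variant_analysis(variants: pd.DataFrame,
                         config: Optional[RunConfig] = None) -> dict:
    """Variant stratification report bundle.

    Needs columns protein_id, position, wt_aa, mut_aa, label, pp2, rsa,
    ss3, ss_change; ddg is optional (its tables are skipped with a notice
    when absent).
    """
    config = config or RunConfig()
    config.validate()
    required = [*mv.VARIANT_REQUIRED_COLUMNS, "ss3", "ss_change"]
    missing = [c for c in required if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing required columns: {missing}")
    bad = variants[(variants["pp2"] < 0) | (variants["pp2"] > 1)]
    if len(bad):
        raise ValueError(f"{len(bad)} variant(s) with pp2 outside [0,1]")
    if not len(variants):
        raise EmptyResultError("variant table is empty")

    w = config.rsa_bin_width_variant
    bundle = {
        "fraction_by_rsa": mv.pathogenic_fraction_table(
            variants, by=("rsa_bin",), rsa_bin_width=w),
        "fraction_by_pp2": mv.pathogenic_fraction_table(
            variants, by=("pp2_bin",)),
        "fraction_by_rsa_pp2": mv.pathogenic_fraction_table(
            variants, by=("rsa_bin", "pp2_bin"), rsa_bin_width=w),
    }

    # break frequency per class (which classes lose their structure most)
    rows = []
    for cls, sub in variants.groupby("ss3"):
        k, n = int(sub["ss_change"].sum()), len(sub)
        lo, hi = st.wilson_ci(k, n)
        rows.append({"ss3": cls, "n_break": k, "n": n, "fraction": k / n,
                     "ci_lo": lo, "ci_hi": hi})
    bundle["break_by_class"] = pd.DataFrame(rows)

    if "ddg" in variants.columns and variants["ddg"].notna().any():
        bundle["ddg_by_label"] = mv.ddg_compare(variants, "label", w)
        bundle["ddg_by_ss_change"] = mv.ddg_compare(variants, "ss_change", w)
        bundle["ddg_by_class"] = mv.ddg_compare(variants, "ss3", w)
    else:
        logger.info("no ddg column: stability tables skipped")
        bundle["ddg_skipped"] = True
    return bundle


def write_bundle(bundle: dict, outdir) -> list[str]:
    """Serialize a report bundle: DataFrames as TSV, scalars as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    meta = {}
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            path = outdir / f"{name}.tsv"
            obj.to_csv(path, sep="\t", index=False, float_format="%.6g")
            written.append(str(path))
            tests = obj.attrs.get("tests")
            if isinstance(tests, pd.DataFrame) and len(tests):
                tpath = outdir / f"{name}_tests.tsv"
                tests.to_csv(tpath, sep="\t", index=False, float_format="%.6g")
                written.append(str(tpath))
        else:
            meta[name] = obj
    if meta:
        path = outdir / "summary.json"
        path.write_text(json.dumps(meta, indent=2, default=str) + "\n")
        written.append(str(path))
    return written
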