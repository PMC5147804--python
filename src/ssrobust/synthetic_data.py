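"""Synthetic inputs with known ground truth.

Every input the pipeline consumes can be generated here: ideal backbone
geometries (helix, strand, antiparallel hairpin, coil) for the structural
annotators, simulated diverged domain pairs with class-dependent
secondary-structure flip rates, RSA distributions, contact models and
indel rates for the comparative statistics, near-identical mutant
sequence sets for the point-mutant scan, and missense-variant cohorts
whose pathogenicity follows a known logistic model.

All generators are deterministic given (config, seed), and every latent
draw is recorded in a ground-truth object so parameter-recovery tests can
compare pipeline estimates against the generating process.

Defaults encode the qualitative structure of real diverged domains:
secondary-structure flip probability ordered coil > strand > helix,
strands more buried than helices, helix residues with more contacts than
strand residues at equal RSA, and flip probability damped multiplicatively
by contact count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from ._geometry import PHI_PSI, build_backbone, transform_domain
from .align_metrics import AnnotatedAlignment
from .structcalc import ResidueAnnotation
from .structio import DomainStructure, PairAlignment, Residue

__all__ = [
    "AA_BACKGROUND",
    "DivergenceConfig",
    "VariantCohortConfig",
    "random_sequence",
    "make_ideal_structure",
    "simulate_domain_pair",
    "simulate_domain_pairs",
    "simulate_mutant_sequence_set",
    "simulate_variant_cohort",
]

#: Natural amino-acid background composition (Robinson-Robinson style).
AA_BACKGROUND = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.091, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.065,
}
_AA = np.array(list(AA_BACKGROUND))
_AA_P = np.array(list(AA_BACKGROUND.values()))
_AA_P = _AA_P / _AA_P.sum()

# twist-free extended conformation (exact 2-fold screw symmetry), found by
# minimizing the residue i -> i+2 frame rotation; allows rigid antiparallel
# pairing at H-bond register over arbitrary strand lengths
STRAND_PHI_PSI = (-138.70716191, 136.15749209)
# rigid placement of the partner strand relative to the first strand's
# (axis, H-bond direction, normal) frame: separation along the H-bond
# direction, register shift along the axis, pleat offset along the normal
_SHEET_TAU, _SHEET_SHIFT_A, _SHEET_SHIFT_W = 4.0, 1.75, 0.0


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """I.i.d. sequence from the natural background composition."""
    return "".join(rng.choice(_AA, size=length, p=_AA_P))


def _mutate_aa(aa: str, rng: np.random.Generator) -> str:
    """A different amino acid, drawn from the background."""
    while True:
        new = str(rng.choice(_AA, p=_AA_P))
        if new != aa:
            return new


# ---------------------------------------------------------------------------
# Ideal geometries

def _sheet_frame(strand: DomainStructure):
    ca = np.array([r.atom("CA").xyz for r in strand.residues])
    o = np.array([r.atom("O").xyz for r in strand.residues])
    c = np.array([r.atom("C").xyz for r in strand.residues])
    a = ca[-2] - ca[2] if len(ca) > 4 else ca[-1] - ca[0]
    a /= np.linalg.norm(a)
    co = (o - c).mean(axis=0)
    co -= (co @ a) * a
    u = co / np.linalg.norm(co)
    w = np.cross(a, u)
    return a, u, w, ca.mean(axis=0)


def _antiparallel_partner(strand: DomainStructure, length: int,
                          start_number: int) -> DomainStructure:
    """Second strand rigidly placed at antiparallel H-bond register."""
    a, u, w, p0 = _sheet_frame(strand)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    rot = np.eye(3) + 2 * (K @ K)          # 180 degrees about u
    t = p0 - rot @ p0 + _SHEET_TAU * u + _SHEET_SHIFT_A * a + _SHEET_SHIFT_W * w
    partner = build_backbone("A" * length, [STRAND_PHI_PSI] * length,
                             start_number=start_number)
    return transform_domain(partner, rot, t)


def make_ideal_structure(kind: str, length: int,
                         seed: Optional[int] = None,
                         sequence: Optional[str] = None) -> DomainStructure:
    """Ideal-geometry backbone of the requested secondary structure.

    kinds: 'helix' (phi/psi -57/-47), 'strand' (extended, twist-free
    screw), 'coil' (seeded random sterically-open dihedrals), 'hairpin'
    (two antiparallel strands at H-bond register joined by a 2-residue
    turn; ``length`` is the length of each strand, even lengths pair
    cleanly).  Coordinates are deterministic given (kind, length, seed).
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "A" * length if kind != "coil" else random_sequence(length, rng)

    if kind == "helix":
        return build_backbone(sequence, [PHI_PSI["helix"]] * length, sid="helix")
    if kind == "strand":
        return build_backbone(sequence, [STRAND_PHI_PSI] * length, sid="strand")
    if kind == "coil":
        # sterically open dihedrals avoiding the helical basin: mix of the
        # extended/PPII region and the left-handed region
        pp = []
        for _ in range(length):
            if rng.random() < 0.7:
                pp.append((rng.uniform(-160, -60), rng.uniform(100, 180)))
            else:
                pp.append((rng.uniform(50, 100), rng.uniform(0, 80)))
        return build_backbone(sequence, pp, sid="coil")
    if kind == "hairpin":
        s1 = build_backbone("A" * length, [STRAND_PHI_PSI] * length,
                            start_number=1)
        s2 = _antiparallel_partner(s1, length, start_number=length + 3)
        # 2-residue turn interpolated between the strand termini; rough
        # geometry on purpose - it must only read as coil
        p_start = s1.residues[-1].atom("C").xyz
        p_end = s2.residues[0].atom("N").xyz
        turn_res = []
        for k in (1, 2):
            f = k / 3.0
            base = (1 - f) * p_start + f * p_end
            jitter = np.array([0.0, 0.0, 1.2 if k == 1 else -1.2])
            from .structio import Atom
            atoms = (
                Atom("N", "N", tuple(base + jitter + [0.6, 0, 0])),
                Atom("CA", "C", tuple(base + jitter)),
                Atom("C", "C", tuple(base + jitter + [-0.6, 0.4, 0])),
                Atom("O", "O", tuple(base + jitter + [-0.6, 1.6, 0])),
            )
            turn_res.append(Residue(length + k, "", "G", atoms))
        residues = list(s1.residues) + turn_res + list(s2.residues)
        return DomainStructure(sid="hairpin", residues=residues)
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# Diverged domain pairs

@dataclass
class DivergenceConfig:
    """Generating process for one diverged domain pair.

    p_flip is the probability that a substituted site changes secondary
    structure, before contact damping; contact_lambda scales the
    multiplicative damping exp(-lambda * z(contacts)).  substitution_prob
    is the per-site substitution probability (the mutation load).
    """

    # default load places pairs in the 10-20% identity window (the densest
    # window of the comparative analysis): substituted sites never retain
    # their amino acid, so expected identity is 1 - substitution_prob
    substitution_prob: float = 0.85
    p_flip: dict = field(default_factory=lambda: {"H": 0.05, "E": 0.15, "C": 0.30})
    flip_to_coil: float = 0.8
    rsa_beta: dict = field(default_factory=lambda: {
        "H": (1.5, 2.0), "E": (1.2, 3.5), "C": (1.8, 1.2)})
    contact_model: dict = field(default_factory=lambda: {
        "H": (10.0, -6.0, 1.5), "E": (8.0, -6.0, 1.5), "C": (6.0, -5.0, 1.5)})
    contact_lambda: float = 0.5
    indel_rate: dict = field(default_factory=lambda: {"H": 0.01, "E": 0.005, "C": 0.03})
    contact_distance_model: dict = field(default_factory=lambda: {
        "H": (3.0, 1.0), "E": (5.0, 15.0), "C": (4.0, 8.0)})  # offset, exp scale
    tm_score: float = 0.8
    unit_length_range: tuple = (4, 15)
    linker_length_range: tuple = (2, 6)
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.substitution_prob <= 1):
            raise ValueError("substitution_prob must be in [0,1]")
        for cls in ("H", "E", "C"):
            if not (0 <= self.p_flip[cls] <= 1):
                raise ValueError("p_flip values must be in [0,1]")
            if self.contact_model[cls][2] < 0:
                raise ValueError("contact noise must be >= 0")
            if not (0 <= self.indel_rate[cls] <= 1):
                raise ValueError("indel rates must be in [0,1]")


def _draw_ss_layout(length: int, cfg: DivergenceConfig,
                    rng: np.random.Generator) -> list[str]:
    """Alternating H/E units separated by coil linkers, truncated to length."""
    out: list[str] = []
    next_structured = "H" if rng.random() < 0.5 else "E"
    while len(out) < length:
        lo, hi = cfg.linker_length_range
        out.extend("C" * int(rng.integers(lo, hi + 1)))
        lo, hi = cfg.unit_length_range
        out.extend(next_structured * int(rng.integers(lo, hi + 1)))
        next_structured = "E" if next_structured == "H" else "H"
    return out[:length]


def simulate_domain_pair(cfg: DivergenceConfig, length: int,
                         seed: Optional[int] = None,
                         pair_id: str = "pair",
                         ) -> tuple[AnnotatedAlignment, dict]:
    """One simulated diverged domain pair plus its ground truth.

    An ancestral domain is drawn (secondary-structure unit layout, amino
    acids, per-class RSA and contacts); each site substitutes with
    probability ``substitution_prob``, and a substituted site flips its
    secondary structure with probability p_flip(class) damped by the
    site's standardized contact count.  Indels are inserted per class
    rates.  The truth record carries every latent draw.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    ss1 = _draw_ss_layout(length, cfg, rng)
    seq1 = random_sequence(length, rng)

    rsa1 = np.empty(length)
    contacts1 = np.empty(length, dtype=int)
    for i, cls in enumerate(ss1):
        a, b = cfg.rsa_beta[cls]
        rsa1[i] = rng.beta(a, b)
        ic, sl, sd = cfg.contact_model[cls]
        contacts1[i] = max(0, int(round(ic + sl * rsa1[i] + rng.normal(0, sd))))

    c_mean, c_sd = contacts1.mean(), max(contacts1.std(), 1e-9)
    z = (contacts1 - c_mean) / c_sd
    p_eff = np.array([
        min(1.0, cfg.p_flip[ss1[i]] * math.exp(-cfg.contact_lambda * z[i]))
        for i in range(length)])

    seq2_chars: list[str] = []
    ss2: list[str] = []
    substituted = np.zeros(length, dtype=bool)
    flipped = np.zeros(length, dtype=bool)
    for i in range(length):
        aa = seq1[i]
        cls2 = ss1[i]
        if rng.random() < cfg.substitution_prob:
            substituted[i] = True
            aa = _mutate_aa(seq1[i], rng)
            if rng.random() < p_eff[i]:
                flipped[i] = True
                if ss1[i] == "C":
                    cls2 = "H" if rng.random() < 0.5 else "E"
                elif rng.random() < cfg.flip_to_coil:
                    cls2 = "C"
                else:
                    cls2 = "E" if ss1[i] == "H" else "H"
        seq2_chars.append(aa)
        ss2.append(cls2)

    rsa2 = np.clip(rsa1 + rng.normal(0, 0.05, size=length), 0, None)
    contacts2 = np.maximum(0, contacts1 + rng.integers(-1, 2, size=length))

    def draw_mcd(cls: str) -> float:
        off, scale = cfg.contact_distance_model[cls]
        return off + rng.exponential(scale)

    ann1 = [ResidueAnnotation(ss3=ss1[i], asa=float("nan"), rsa=float(rsa1[i]),
                              n_contacts=int(contacts1[i]),
                              mean_contact_distance=draw_mcd(ss1[i]))
            for i in range(length)]
    ann2 = [ResidueAnnotation(ss3=ss2[i], asa=float("nan"), rsa=float(rsa2[i]),
                              n_contacts=int(contacts2[i]),
                              mean_contact_distance=draw_mcd(ss2[i]))
            for i in range(length)]

    # columns: ancestral sites aligned; indel events inject gap-opposed
    # residues (deletions from side 2, insertions into side 2)
    columns: list[tuple[Optional[int], Optional[int]]] = []
    keep2 = np.ones(length, dtype=bool)
    insert_after = np.zeros(length, dtype=bool)
    n_indel = {"H": 0, "E": 0, "C": 0}
    for i in range(length):
        rate = cfg.indel_rate[ss1[i]]
        if rng.random() < rate:
            if rng.random() < 0.5:
                keep2[i] = False
            else:
                insert_after[i] = True
            n_indel[ss1[i]] += 1

    seq2_final: list[str] = []
    ann2_final: list[ResidueAnnotation] = []
    j = 0
    for i in range(length):
        if keep2[i]:
            columns.append((i, j))
            seq2_final.append(seq2_chars[i])
            ann2_final.append(ann2[i])
            j += 1
        else:
            columns.append((i, None))
        if insert_after[i]:
            cls = ss1[i]
            columns.append((None, j))
            seq2_final.append(_mutate_aa("X" if not seq2_chars else seq2_chars[i], rng))
            ann2_final.append(ResidueAnnotation(
                ss3=cls, asa=float("nan"),
                rsa=float(rng.beta(*cfg.rsa_beta[cls])),
                n_contacts=int(max(0, round(cfg.contact_model[cls][0]
                                            + rng.normal(0, cfg.contact_model[cls][2])))),
                mean_contact_distance=draw_mcd(cls)))
            j += 1

    pa = PairAlignment(f"{pair_id}_1", f"{pair_id}_2", cfg.tm_score, columns,
                       seq1=seq1, seq2="".join(seq2_final))
    aln = AnnotatedAlignment(pa, ann1, ann2_final)

    truth = {
        "length": length,
        "ss1": "".join(ss1), "ss2": "".join(ss2),
        "substituted": substituted, "flipped": flipped,
        "p_eff": p_eff, "rsa1": rsa1, "contacts1": contacts1,
        "n_sub": int(substituted.sum()),
        "n_indel": n_indel,
        "per_class": {
            cls: {
                "sites": int(sum(1 for s in ss1 if s == cls)),
                "subs": int(sum(substituted[i] for i in range(length) if ss1[i] == cls)),
                "flips": int(sum(flipped[i] for i in range(length) if ss1[i] == cls)),
            } for cls in "HEC"},
    }
    return aln, truth


def simulate_domain_pairs(cfg: DivergenceConfig, n_pairs: int, length: int,
                          ) -> list[tuple[AnnotatedAlignment, dict]]:
    """Independent pairs with per-pair seeds derived from cfg.seed."""
    root = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(n_pairs)]
    return [simulate_domain_pair(cfg, length, seed=s, pair_id=f"pair{i}")
            for i, s in enumerate(seeds)]


# ---------------------------------------------------------------------------
# Near-identical mutant sequence sets

def simulate_mutant_sequence_set(
    n_groups: int, group_size: int, length: int = 200,
    n_sub_range: tuple[int, int] = (1, 3),
    min_id: float = 0.98, min_len: int = 64, min_spacing: int = 10,
    seed: int = 0,
) -> tuple[dict[str, str], list[tuple]]:
    """Groups of near-identical sequences plus the expected scan output.

    Each group has a base sequence and ``group_size - 1`` variants carrying
    1-3 substitutions at recorded positions.  The truth list contains the
    (group representative id, position, wt, mut) keys expected to survive
    the full scan - pair identity threshold, indel-free substitution
    calling, the >= ``min_spacing`` rule and homology-group redundancy
    collapse - computed by direct positional comparison, independently of
    the alignment-based pipeline.
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    group_members: list[list[str]] = []
    for g in range(n_groups):
        base = random_sequence(length, rng)
        names = [f"g{g:03d}_s{k}" for k in range(group_size)]
        seqs[names[0]] = base
        for name in names[1:]:
            n_sub = int(rng.integers(n_sub_range[0], n_sub_range[1] + 1))
            pos = rng.choice(length, size=n_sub, replace=False)
            s = list(base)
            for p in pos:
                s[p] = _mutate_aa(base[p], rng)
            seqs[name] = "".join(s)
        group_members.append(names)

    # ground truth by direct bookkeeping (positional hamming comparison)
    truth_keys: set[tuple] = set()
    for names in group_members:
        # collapse exact duplicates the same way the scan will (keep first)
        uniq: list[str] = []
        seen: set[str] = set()
        for name in names:
            if seqs[name] not in seen:
                seen.add(seqs[name])
                uniq.append(name)
        rep = min(uniq)
        for ia in range(len(uniq)):
            for ib in range(ia + 1, len(uniq)):
                a, b = uniq[ia], uniq[ib]
                diffs = [p for p in range(length) if seqs[a][p] != seqs[b][p]]
                if not diffs or 1 - len(diffs) / length < min_id:
                    continue
                if len(diffs) > 1:
                    diffs = [p for p in diffs
                             if min(abs(p - q) for q in diffs if q != p) >= min_spacing]
                for p in diffs:
                    truth_keys.add((rep, p, seqs[a][p], seqs[b][p]))
    return seqs, sorted(truth_keys)


# ---------------------------------------------------------------------------
# Variant cohorts

@dataclass
class VariantCohortConfig:
    """Logistic generating model for a missense-variant cohort.

    P(pathogenic) = sigmoid(intercept + b_ssbreak*break + b_rsa*rsa +
    b_ddg*ddg); ddG is drawn conditional on the break flag, the PolyPhen-2
    score conditional on the realized label.
    """

    n: int = 20000
    intercept: float = -2.0
    beta_ssbreak: float = 1.2
    beta_rsa: float = -1.5
    beta_ddg: float = 0.35
    ddg_break: tuple = (2.5, 1.2)       # mean, sd (kcal/mol)
    ddg_nobreak: tuple = (0.6, 1.0)
    break_prob: dict = field(default_factory=lambda: {"H": 0.05, "E": 0.12, "C": 0.15})
    class_probs: dict = field(default_factory=lambda: {"H": 0.35, "E": 0.25, "C": 0.40})
    rsa_beta: dict = field(default_factory=lambda: {
        "H": (1.5, 2.0), "E": (1.2, 3.5), "C": (1.8, 1.2)})
    pp2_pathogenic: tuple = (5.0, 1.2)  # beta shape parameters
    pp2_neutral: tuple = (0.8, 3.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for m, s in (self.ddg_break, self.ddg_nobreak):
            if s <= 0:
                raise ValueError("ddG sds must be > 0")
        for v in self.break_prob.values():
            if not (0 <= v <= 1):
                raise ValueError("break probabilities must be in [0,1]")


def simulate_variant_cohort(cfg: VariantCohortConfig,
                            seed: Optional[int] = None):
    """Variant table (pandas DataFrame) plus the latent ground truth."""
    import pandas as pd

    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n

    classes = rng.choice(list(cfg.class_probs), size=n,
                         p=np.array(list(cfg.class_probs.values()))
                         / sum(cfg.class_probs.values()))
    rsa = np.array([rng.beta(*cfg.rsa_beta[c]) for c in classes])
    brk = np.array([rng.random() < cfg.break_prob[c] for c in classes])
    ddg = np.where(brk,
                   rng.normal(cfg.ddg_break[0], cfg.ddg_break[1], n),
                   rng.normal(cfg.ddg_nobreak[0], cfg.ddg_nobreak[1], n))
    logit = (cfg.intercept + cfg.beta_ssbreak * brk.astype(float)
             + cfg.beta_rsa * rsa + cfg.beta_ddg * ddg)
    p_path = 1.0 / (1.0 + np.exp(-logit))
    pathogenic = rng.random(n) < p_path
    pp2 = np.where(pathogenic,
                   rng.beta(*cfg.pp2_pathogenic, n),
                   rng.beta(*cfg.pp2_neutral, n))

    wt = rng.choice(_AA, size=n, p=_AA_P)
    mut = np.array([_mutate_aa(a, rng) for a in wt])
    df = pd.DataFrame({
        "protein_id": [f"P{i // 50:05d}" for i in range(n)],
        "position": np.arange(n) % 400,
        "wt_aa": wt, "mut_aa": mut,
        "label": np.where(pathogenic, "pathogenic", "neutral"),
        "pp2": np.clip(pp2, 0, 1),
        "rsa": rsa,
        "ss3": classes,
        "ss_change": brk,
        "ddg": ddg,
    })
    truth = {"config": asdict(cfg), "p_pathogenic": p_path, "break": brk,
             "classes": classes, "rsa": rsa, "ddg": ddg}
    return df, truth
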