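"""Degenerate primer design from conserved protein motifs.

Protein-level motif occurrences are mapped codon-wise onto each species'
coding sequence, the stacked 3w-nt blocks are collapsed into a degenerate
IUPAC consensus (per-column union of observed bases — this, not codon-table
back-translation, is what keeps degeneracy low when variation is mostly
synonymous), and primer windows are selected under physical constraints
(length, degeneracy cap, Wallace Tm range, non-degenerate 3' end).  All
ordered motif pairs on a reference transcript are then enumerated under
amplicon-size constraints and ranked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import iupac
from .motifs import MotifOccurrence, MotifSet
from .seqalign import SequenceRecord, translate_cds


@dataclass
class CodingPair:
    """A protein sequence and its coding sequence with verified correspondence."""

    id: str
    protein: SequenceRecord
    cds: SequenceRecord

    def __post_init__(self):
        aa = translate_cds(self.cds.residues)
        if aa != self.protein.residues:
            raise ValueError(
                f"CDS of {self.id!r} does not translate to its protein "
                f"(translated {len(aa)} aa vs protein {len(self.protein.residues)} aa)"
            )


def pair_records(
    proteins: list[SequenceRecord], cdss: list[SequenceRecord]
) -> list[CodingPair]:
    """Match protein and CDS records by id and validate codon correspondence."""
    cds_by_id = {c.id: c for c in cdss}
    out = []
    for p in proteins:
        if p.id not in cds_by_id:
            raise ValueError(f"no CDS for protein {p.id!r}")
        out.append(CodingPair(p.id, p, cds_by_id[p.id]))
    return out


def map_motif_to_cds(occ: MotifOccurrence, cp: CodingPair) -> tuple[int, int]:
    """0-based half-open nucleotide interval of a protein motif occurrence."""
    if occ.seq_id != cp.id:
        raise ValueError(f"occurrence id {occ.seq_id!r} != coding pair {cp.id!r}")
    w = len(occ.site)
    start, end = 3 * occ.start, 3 * (occ.start + w)
    if end > len(cp.cds.residues):
        raise ValueError(f"motif interval [{start},{end}) exceeds CDS of {cp.id!r}")
    return start, end


@dataclass
class ConservedBlock:
    """Stacked per-species nucleotide substrings under one protein motif."""

    motif_rank: int
    substrings: dict[str, str]  # species id -> 3w-nt string
    column_sets: list[frozenset[str]]  # per column, union of observed bases


def build_block(
    occs: list[MotifOccurrence], pairs: list[CodingPair], motif_rank: int = 0
) -> ConservedBlock:
    """Union the codon blocks of one motif across species.

    N in a CDS is ignored when forming column base-sets; a column observed
    only as N is an error.
    """
    if len(occs) < 2:
        raise ValueError("need occurrences from at least 2 species")
    widths = {len(o.site) for o in occs}
    if len(widths) != 1:
        raise ValueError(f"differing motif widths in block: {sorted(widths)}")
    by_id = {cp.id: cp for cp in pairs}
    subs: dict[str, str] = {}
    for occ in occs:
        cp = by_id[occ.seq_id]
        s, e = map_motif_to_cds(occ, cp)
        subs[occ.seq_id] = cp.cds.residues[s:e]
    length = 3 * widths.pop()
    sets = []
    for col in range(length):
        bases = {sub[col] for sub in subs.values()} - {"N"}
        if not bases:
            raise ValueError(f"column {col} contains only N")
        sets.append(frozenset(bases))
    return ConservedBlock(motif_rank=motif_rank, substrings=subs, column_sets=sets)


def degenerate_consensus(block: ConservedBlock) -> str:
    """IUPAC string encoding each column's observed base set."""
    return "".join(iupac.consensus_code(s) for s in block.column_sets)


@dataclass
class DesignConfig:
    """Primer design constraints; all values overridable."""

    len_min: int = 18
    len_max: int = 22
    degeneracy_cap: int = 64
    tm_min: float = 45.0  # Wallace Tm bounds over all expansions, degC
    tm_max: float = 65.0
    three_prime_clean: int = 2  # last positions that must be non-degenerate
    amp_min: int = 80
    amp_max: int = 300
    amp_target: int = 150
    max_product: int = 3000
    w_degeneracy: float = 1.0  # pair-score weights
    w_amplicon: float = 0.1
    w_tm_diff: float = 1.0


def wallace_tm_range(seq: str) -> tuple[float, float]:
    """Min/max Wallace Tm (2(A+T)+4(G+C)) over all expansions of an IUPAC string."""
    gmin, gmax = _gc_count_range(seq)
    n = len(seq)
    # 2(A+T) + 4(G+C) = 2n + 2·(G+C)
    return 2.0 * n + 2.0 * gmin, 2.0 * n + 2.0 * gmax


def _gc_count_range(seq: str) -> tuple[int, int]:
    gmin = gmax = 0
    for c in seq:
        bases = iupac.CODE_TO_BASES[c]
        if not bases & {"A", "T"}:
            gmin += 1
        if bases & {"G", "C"}:
            gmax += 1
    return gmin, gmax


def gc_range_pct(seq: str) -> tuple[float, float]:
    gmin, gmax = _gc_count_range(seq)
    return 100.0 * gmin / len(seq), 100.0 * gmax / len(seq)


@dataclass
class DegeneratePrimer:
    """A degenerate oligo with direction and provenance.

    For reverse primers ``iupac`` is already the reverse complement of the
    template-strand window; ``window`` stores the plus-strand (template)
    offsets of the footprint within the source consensus.
    """

    iupac: str
    direction: str  # "forward" | "reverse"
    motif_rank: int = -1
    window: tuple[int, int] = (0, 0)  # half-open offsets in the source consensus

    def __post_init__(self):
        self.degeneracy = iupac.degeneracy(self.iupac)
        self.tm_range_c = wallace_tm_range(self.iupac)
        self.gc_range = gc_range_pct(self.iupac)

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def tm_mid(self) -> float:
        return 0.5 * (self.tm_range_c[0] + self.tm_range_c[1])


@dataclass
class NoPrimer:
    """Typed no-feasible-window result with per-constraint elimination counts."""

    direction: str
    motif_rank: int
    reasons: dict[str, int]

    def __bool__(self) -> bool:
        return False


def choose_primer_window(
    consensus: str,
    direction: str,
    cfg: DesignConfig | None = None,
    motif_rank: int = -1,
):
    """Best primer window within a degenerate consensus.

    All windows with length in [len_min, len_max] are enumerated; windows are
    discarded if (after reverse-complementing, for reverse primers) the last
    ``three_prime_clean`` positions are degenerate, degeneracy exceeds the
    cap, or the Wallace Tm range leaves [tm_min, tm_max].  Among survivors the
    window minimizing (degeneracy, Tm spread, leftmost start) wins.  Returns a
    NoPrimer result (not an exception) when nothing survives.
    """
    cfg = cfg or DesignConfig()
    if len(consensus) < cfg.len_min:
        return NoPrimer(direction, motif_rank, {"too_short": 1})
    reasons = {"three_prime": 0, "degeneracy": 0, "tm": 0}
    best = None
    for length in range(cfg.len_min, cfg.len_max + 1):
        for start in range(0, len(consensus) - length + 1):
            window = consensus[start : start + length]
            primer = iupac.revcomp(window) if direction == "reverse" else window
            tail = primer[-cfg.three_prime_clean :] if cfg.three_prime_clean else ""
            if any(len(iupac.CODE_TO_BASES[c]) > 1 for c in tail):
                reasons["three_prime"] += 1
                continue
            deg = iupac.degeneracy(primer)
            if deg > cfg.degeneracy_cap:
                reasons["degeneracy"] += 1
                continue
            tm_lo, tm_hi = wallace_tm_range(primer)
            if tm_lo < cfg.tm_min or tm_hi > cfg.tm_max:
                reasons["tm"] += 1
                continue
            key = (deg, tm_hi - tm_lo, start, length)
            if best is None or key < best[0]:
                best = (key, primer, start, length)
    if best is None:
        return NoPrimer(direction, motif_rank, reasons)
    _, primer, start, length = best
    return DegeneratePrimer(
        iupac=primer,
        direction=direction,
        motif_rank=motif_rank,
        window=(start, start + length),
    )


@dataclass
class PrimerPair:
    fwd: DegeneratePrimer
    rev: DegeneratePrimer
    amplicon_bp: dict  # template id -> product length in bp
    score: float

    def __post_init__(self):
        self.combined_degeneracy = self.fwd.degeneracy * self.rev.degeneracy


def enumerate_pairs(
    motifset: MotifSet,
    pairs: list[CodingPair],
    reference: str,
    cfg: DesignConfig | None = None,
) -> list[PrimerPair]:
    """All feasible ordered motif-pair primer combinations on a reference CDS.

    For every motif pair (i upstream of j on the reference), the forward
    primer comes from motif i's block consensus and the reverse primer is the
    reverse complement of a window in motif j's consensus.  Product length is
    footprint-inclusive: 5' of the forward site to 5' of the reverse site on
    the plus strand.  Pairs outside [amp_min, amp_max] are dropped; survivors
    are scored (ascending is better) by a weighted sum of combined degeneracy,
    distance to the target amplicon and Tm difference.
    """
    cfg = cfg or DesignConfig()
    if reference not in {cp.id for cp in pairs}:
        raise ValueError(f"reference {reference!r} not among coding pairs")
    ref_cp = next(cp for cp in pairs if cp.id == reference)

    designs = []  # (ref_nt_start, fwd primer|NoPrimer, rev primer|NoPrimer)
    for rank, (model, occs) in enumerate(motifset):
        ref_occ = next((o for o in occs if o.seq_id == reference), None)
        if ref_occ is None:
            continue
        block = build_block(occs, pairs, motif_rank=rank)
        consensus = degenerate_consensus(block)
        nt_start, _ = map_motif_to_cds(ref_occ, ref_cp)
        fwd = choose_primer_window(consensus, "forward", cfg, motif_rank=rank)
        rev = choose_primer_window(consensus, "reverse", cfg, motif_rank=rank)
        designs.append((nt_start, fwd, rev))

    out = []
    for si, fwd_i, _ in designs:
        if not fwd_i:
            continue
        for sj, _, rev_j in designs:
            if sj <= si or not rev_j:
                continue
            fwd_5p = si + fwd_i.window[0]
            rev_5p = sj + rev_j.window[1] - 1
            amplicon = rev_5p - fwd_5p + 1
            if amplicon < len(fwd_i) + len(rev_j):
                continue
            if not (cfg.amp_min <= amplicon <= cfg.amp_max):
                continue
            score = (
                cfg.w_degeneracy * fwd_i.degeneracy * rev_j.degeneracy
                + cfg.w_amplicon * abs(amplicon - cfg.amp_target)
                + cfg.w_tm_diff * abs(fwd_i.tm_mid - rev_j.tm_mid)
            )
            out.append(
                PrimerPair(
                    fwd=fwd_i,
                    rev=rev_j,
                    amplicon_bp={reference: amplicon},
                    score=score,
                )
            )
    out.sort(key=lambda p: (p.score, p.fwd.motif_rank, p.rev.motif_rank))
    return out


REPORT_COLUMNS = [
    "gene_name",
    "primer",
    "sequence_5to3",
    "amplicon_bp",
    "degeneracy",
    "tm_min_c",
    "tm_max_c",
    "gc_min_pct",
    "gc_max_pct",
]


def design_report(pairs: list[PrimerPair], gene_name: str = "gene") -> pd.DataFrame:
    """Tabular report: one row per primer, amplicon size on both rows of a pair."""
    rows = []
    for idx, pp in enumerate(pairs):
        suffix = "" if idx == 0 else str(idx + 1)
        amp = next(iter(pp.amplicon_bp.values())) if pp.amplicon_bp else pd.NA
        for tag, primer in (("Fwd", pp.fwd), ("Rev", pp.rev)):
            rows.append(
                {
                    "gene_name": gene_name,
                    "primer": f"{gene_name}{tag}{suffix}",
                    "sequence_5to3": primer.iupac,
                    "amplicon_bp": amp,
                    "degeneracy": primer.degeneracy,
                    "tm_min_c": primer.tm_range_c[0],
                    "tm_max_c": primer.tm_range_c[1],
                    "gc_min_pct": round(primer.gc_range[0], 1),
                    "gc_max_pct": round(primer.gc_range[1], 1),
                }
            )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
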