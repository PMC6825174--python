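"""Primer physical QC and local in-silico PCR.

The scanner below is a *local* specificity surrogate: it searches user-supplied
template sequences for primer binding sites under IUPAC set-matching with a
mismatch budget and a mismatch-free 3' anchor, then pairs plus-strand forward
sites with minus-strand reverse sites to predict products.  It does not query
any external database.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import iupac
from .primers import DegeneratePrimer, gc_range_pct, wallace_tm_range


@dataclass
class QCReport:
    iupac: str
    degeneracy: int
    gc_range: tuple[float, float]  # percent over expansions
    tm_range_c: tuple[float, float]  # Wallace rule over expansions
    max_self_complement_run: int
    longest_mononucleotide_run: int


def _can_pair(code_a: str, code_b: str) -> bool:
    """True if some expansion of code_a pairs Watson–Crick with one of code_b."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    return any(
        comp[a] in iupac.CODE_TO_BASES[code_b] for a in iupac.CODE_TO_BASES[code_a]
    )


def qc(primer) -> QCReport:
    """Physical checks for a primer (DegeneratePrimer or raw IUPAC string)."""
    seq = primer.iupac if hasattr(primer, "iupac") else primer
    n = len(seq)
    # longest run of a single achievable concrete base
    mono = 0
    for base in "ACGT":
        run = best = 0
        for c in seq:
            run = run + 1 if base in iupac.CODE_TO_BASES[c] else 0
            best = max(best, run)
        mono = max(mono, best)
    # longest self-complementary stretch: substring that can pair, antiparallel,
    # with another substring of the same primer (exhaustive O(n^3) check)
    selfc = 0
    for i in range(n):
        for j in range(n):
            k = 0
            while i + k < n and j - k >= 0 and _can_pair(seq[i + k], seq[j - k]):
                k += 1
            selfc = max(selfc, k)
    return QCReport(
        iupac=seq,
        degeneracy=iupac.degeneracy(seq),
        gc_range=gc_range_pct(seq),
        tm_range_c=wallace_tm_range(seq),
        max_self_complement_run=selfc,
        longest_mononucleotide_run=mono,
    )


@dataclass
class BindingSite:
    template_id: str
    strand: str  # "+" | "-"
    start: int  # 0-based plus-strand coordinate of the footprint start
    mismatches: int
    three_prime_exact: bool = True
    end: int = 0  # half-open footprint end on the plus strand


@dataclass
class Amplicon:
    template_id: str
    start: int  # 0-based half-open on the plus strand, primer-inclusive
    end: int
    fwd_site: BindingSite
    rev_site: BindingSite

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def _scan_plus(pattern: str, template: str, template_id: str, strand: str,
               max_mismatch: int, anchor_positions) -> list[BindingSite]:
    """Scan the plus strand for `pattern`; anchor_positions (offsets within the
    footprint) must match exactly.  Template N never matches."""
    L, T = len(pattern), len(template)
    sites = []
    for s in range(T - L + 1):
        mm = 0
        anchored = True
        for k in range(L):
            if not iupac.matches(pattern[k], template[s + k]):
                if k in anchor_positions:
                    anchored = False
                    break
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            if anchored and mm <= max_mismatch:
                sites.append(BindingSite(template_id, strand, s, mm, True, s + L))
    return sites


def find_binding_sites(
    primer,
    template,
    max_mismatch: int = 0,
    three_prime_exact_len: int = 3,
) -> list[BindingSite]:
    """All binding sites of a (possibly degenerate) primer on both strands.

    A template position matches if its base is in the primer code's set; N in
    the template never matches.  The 3'-most ``three_prime_exact_len``
    positions must be mismatch-free.  Sites are sorted by (strand, start).
    """
    seq = primer.iupac if hasattr(primer, "iupac") else primer
    tid = getattr(template, "id", "template")
    tseq = template.residues if hasattr(template, "residues") else template
    tseq = tseq.upper()
    if len(seq) > len(tseq):
        return []
    L = len(seq)
    anchor = min(three_prime_exact_len, L)
    # plus strand: primer 3' end is the footprint's last position
    plus_anchor = set(range(L - anchor, L))
    sites = _scan_plus(seq, tseq, tid, "+", max_mismatch, plus_anchor)
    # minus strand: the primer binds the reverse strand; its reverse complement
    # appears on the plus strand, with the primer 3' end at the footprint START
    rc = iupac.revcomp(seq)
    minus_anchor = set(range(anchor))
    sites += _scan_plus(rc, tseq, tid, "-", max_mismatch, minus_anchor)
    sites.sort(key=lambda x: (x.strand, x.start))
    return sites


def predict_amplicons(
    fwd,
    rev,
    template,
    max_mismatch: int = 0,
    three_prime_exact_len: int = 3,
    max_product: int = 3000,
) -> list[Amplicon]:
    """Products from all compatible (forward +, reverse −) site combinations.

    Product length is primer-inclusive: reverse-site 5' coordinate minus
    forward-site 5' coordinate plus one on the plus strand.
    """
    fsites = [
        s
        for s in find_binding_sites(fwd, template, max_mismatch, three_prime_exact_len)
        if s.strand == "+"
    ]
    rsites = [
        s
        for s in find_binding_sites(rev, template, max_mismatch, three_prime_exact_len)
        if s.strand == "-"
    ]
    fwd_len = len(fwd.iupac if hasattr(fwd, "iupac") else fwd)
    rev_len = len(rev.iupac if hasattr(rev, "iupac") else rev)
    tid = getattr(template, "id", "template")
    out = []
    for fs in fsites:
        for rs in rsites:
            length = rs.end - fs.start  # (rev 5' coord) − (fwd 5' coord) + 1
            if length < fwd_len + rev_len or length > max_product:
                continue
            out.append(Amplicon(tid, fs.start, rs.end, fs, rs))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def amplicon_report(amplicons: list[Amplicon]) -> pd.DataFrame:
    """TSV-ready table; coordinates 1-based inclusive for human consumption."""
    rows = [
        {
            "template": a.template_id,
            "start": a.start + 1,
            "end": a.end,
            "length_bp": a.length_bp,
            "fwd_mismatches": a.fwd_site.mismatches,
            "rev_mismatches": a.rev_site.mismatches,
        }
        for a in amplicons
    ]
    return pd.DataFrame(
        rows,
        columns=["template", "start", "end", "length_bp", "fwd_mismatches", "rev_mismatches"],
    )
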