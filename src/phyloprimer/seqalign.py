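"""Sequence ingestion, pairwise alignment, distance matrices and NJ trees.

This module covers the phylogenetic front end of the primer-design workflow:
homologous protein (or CDS) sequences are read from FASTA, aligned pairwise
under an affine-gap global model, converted into a p-distance matrix, and a
neighbor-joining tree is built so that a phylogenetically coherent subset of
species can be selected for motif discovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_CHARS = frozenset("ACGTN")


@dataclass
class SequenceRecord:
    """A named sequence over the protein or DNA alphabet."""

    id: str
    residues: str
    alphabet: str = "protein"  # "protein" | "dna"
    species: str = ""

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"empty sequence for {self.id!r}")
        if self.alphabet not in ("protein", "dna"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = PROTEIN_CHARS if self.alphabet == "protein" else DNA_CHARS
        for i, c in enumerate(self.residues):
            if c not in allowed:
                raise ValueError(
                    f"illegal {self.alphabet} character {c!r} at position {i} in {self.id!r}"
                )
        if not self.species:
            self.species = self.id

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords.

    Line wrapping and trailing whitespace are tolerated; case is normalized to
    upper.  The species field is taken from the header description after the
    id, when present.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq).strip().upper(),
                alphabet=alphabet,
                species=desc or rec.id,
            )
        )
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = r.id if r.species in ("", r.id) else f"{r.id} {r.species}"
            fh.write(f">{header}\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")


_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)


def translate_cds(cds: str) -> str:
    """Translate a coding sequence under the standard genetic code.

    A terminal stop codon is dropped; an internal stop is an error; any codon
    containing N translates to X.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aas = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if "N" in codon:
            aas.append("X")
        elif codon in _STOP_CODONS:
            if i == n_codons - 1:
                break
            raise ValueError(f"internal stop codon {codon} at nt {3 * i}")
        else:
            aas.append(_CODON_TABLE[codon])
    return "".join(aas)


@dataclass
class PairwiseAlignment:
    ids: tuple[str, str]
    aligned: tuple[str, str]
    score: float
    identity_pct: float


def _make_aligner(alphabet: str, matrix: str | None, gap_open: float, gap_extend: float):
    aligner = PairwiseAligner()
    aligner.mode = "global"
    name = matrix or ("BLOSUM62" if alphabet == "protein" else "NUC.4.4")
    aligner.substitution_matrix = substitution_matrices.load(name)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix: str | None = None,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps (BLOSUM62 default for protein).

    identity_pct is computed over aligned columns with at least one residue
    (dual-gap columns, which cannot occur in an optimal pairwise alignment,
    are excluded by definition).
    """
    if a.alphabet != b.alphabet:
        raise ValueError(f"alphabet mismatch: {a.alphabet} vs {b.alphabet}")
    aligner = _make_aligner(a.alphabet, matrix, gap_open, gap_extend)
    aln = aligner.align(a.residues, b.residues)[0]
    sa, sb = str(aln[0]), str(aln[1])
    cols = sum(1 for x, y in zip(sa, sb) if x != "-" or y != "-")
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return PairwiseAlignment(
        ids=(a.id, b.id),
        aligned=(sa, sb),
        score=float(aln.score),
        identity_pct=100.0 * matches / cols,
    )


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal not zero")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            labels = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [line.rstrip("\n").split("\t")[1:] for line in fh if line.strip()]
        return cls(labels, np.array(rows, dtype=float))


def distance_matrix(seqs: list[SequenceRecord]) -> DistanceMatrix:
    """Pairwise p-distances (1 − identity/100) from global alignments."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[i], seqs[j])
            d[i, j] = d[j, i] = 1.0 - aln.identity_pct / 100.0
    return DistanceMatrix([s.id for s in seqs], d)


class PhyloTree:
    """Unrooted tree with branch lengths, backed by an undirected graph."""

    def __init__(self, graph: nx.Graph, leaves: list[str]):
        self.graph = graph
        self.leaves = list(leaves)

    def leaf_distance(self, a: str, b: str) -> float:
        return nx.shortest_path_length(self.graph, a, b, weight="length")

    def path_metric(self) -> DistanceMatrix:
        n = len(self.leaves)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = self.leaf_distance(self.leaves[i], self.leaves[j])
        return DistanceMatrix(self.leaves, d)

    def neighbors_of(self, node: str) -> list[str]:
        return sorted(self.graph.neighbors(node))

    def are_sisters(self, a: str, b: str) -> bool:
        """True if two leaves attach to the same internal node (cherry)."""
        na, nb = list(self.graph.neighbors(a)), list(self.graph.neighbors(b))
        return len(na) == 1 and len(nb) == 1 and na[0] == nb[0]

    def to_newick(self) -> str:
        # root arbitrarily at the internal node with the lexicographically
        # smallest name (or the first leaf's neighbor for n=2 edge case)
        internal = sorted(n for n in self.graph if n not in self.leaves)
        root = internal[0] if internal else self.leaves[0]

        def render(node, parent):
            children = [n for n in self.graph.neighbors(node) if n != parent]
            if not children:
                label = node
            else:
                label = "(" + ",".join(render(c, node) for c in sorted(children)) + ")"
                if node in self.leaves:
                    label += node
            if parent is None:
                return label
            blen = self.graph[node][parent]["length"]
            return f"{label}:{blen:.6f}"

        return render(root, None) + ";"


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    On an additive (tree-metric) input the reconstructed tree's path-length
    metric reproduces the input exactly.  Negative branch-length estimates are
    clamped to zero with a warning.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    active = list(D.labels)
    dist = {
        (a, b): float(D.d[i, j])
        for i, a in enumerate(D.labels)
        for j, b in enumerate(D.labels)
    }
    G = nx.Graph()
    clamped = False
    next_internal = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(active) > 2:
        r = {a: sum(dist[(a, b)] for b in active if b != a) for a in active}
        m = len(active)
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (m - 2) * dist[(a, b)] - r[a] - r[b]
                key = (q, a, b)  # deterministic tie-break by label pair
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = dist[(a, b)]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        u = f"_nj{next_internal}"
        next_internal += 1
        G.add_edge(a, u, length=clamp(la))
        G.add_edge(b, u, length=clamp(lb))
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist[(a, c)] + dist[(b, c)] - dab)
            dist[(u, c)] = dist[(c, u)] = duc
        active = [c for c in active if c not in (a, b)] + [u]

    a, b = active
    G.add_edge(a, b, length=clamp(dist[(a, b)]))
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0", stacklevel=2)
    return PhyloTree(G, D.labels)


def select_relatives(
    D: DistanceMatrix,
    focal: str,
    k: int | None = None,
    max_dist: float | None = None,
) -> list[str]:
    """Ids sorted by ascending distance to the focal sequence (focal first).

    Exactly one of ``k`` (keep the k closest including focal) or ``max_dist``
    (keep all within the threshold) must be given.  Ties break
    lexicographically by id.
    """
    if (k is None) == (max_dist is None):
        raise ValueError("give exactly one of k or max_dist")
    if focal not in D.labels:
        raise ValueError(f"focal id {focal!r} not in distance matrix")
    fi = D.labels.index(focal)
    order = sorted(
        range(len(D.labels)),
        key=lambda j: (D.d[fi, j] if j != fi else -1.0, D.labels[j]),
    )
    ids = [D.labels[j] for j in order]
    if k is not None:
        return ids[:k]
    return [lab for lab, j in zip(ids, order) if (j == fi or D.d[fi, j] <= max_dist)]
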