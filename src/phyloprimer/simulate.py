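"""Deterministic synthetic-data generators with recorded ground truth.

Three generators emulate the data surfaces of the workflow:

* homolog families — an ancestral protein evolved down a star phylogeny with
  per-species substitution rates, planted ungapped motifs drawn at a stated
  per-column conservation, and codon-consistent CDS where synonymous "wobble"
  is restricted to third positions (codons are drawn only within the canonical
  codon box, i.e. sharing their first two bases);
* expression matrices — a latent-factor module model with designated hub
  genes loading on two modules (hub–bridge structure);
* Ct tables — generated by inverting the 2^-ddCt formula around a baseline,
  so the planted fold changes are exactly recoverable at zero noise.

Every generator is a pure function of its spec (same seed, byte-identical
output) and returns a truth dictionary sufficient to score recovery
experiments without re-deriving anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .motifs import AMINO_ACIDS
from .seqalign import SequenceRecord, _CODON_TABLE


@dataclass
class PlantedMotif:
    consensus: str  # protein consensus, width 6-10
    start: int  # aa offset, same in every species (no indels simulated)
    conservation: float = 0.9  # per-column probability of the consensus residue

    def __post_init__(self):
        if not 6 <= len(self.consensus) <= 10:
            raise ValueError("motif width must be in [6, 10]")
        if not 0 < self.conservation <= 1:
            raise ValueError("conservation must be in (0, 1]")


@dataclass
class FamilySpec:
    n_species: int = 6
    protein_length: int = 200
    rates: list[float] | None = None  # per-species branch substitution rate
    motifs: list[PlantedMotif] = field(default_factory=list)
    synonymous_wobble: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.rates is None:
            self.rates = [0.05 + 0.02 * i for i in range(self.n_species)]
        if len(self.rates) != self.n_species:
            raise ValueError("one rate per species required")
        spans = sorted((m.start, m.start + len(m.consensus)) for m in self.motifs)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("planted motifs overlap")
        if spans and spans[-1][1] > self.protein_length:
            raise ValueError("motif exceeds protein length")

    @classmethod
    def from_yaml(cls, path) -> "FamilySpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["motifs"] = [PlantedMotif(**m) for m in raw.get("motifs", [])]
        return cls(**raw)


# canonical codon and its "box" (synonymous codons sharing the first 2 nt)
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(_CODON_TABLE.items()):
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
_CANONICAL = {aa: codons[0] for aa, codons in _CODONS_BY_AA.items()}
_BOX = {
    aa: [c for c in codons if c[:2] == _CANONICAL[aa][:2]]
    for aa, codons in _CODONS_BY_AA.items()
}


def simulate_family(spec: FamilySpec):
    """Simulate a homolog family.

    Returns (protein records, CDS records, truth).  Truth records the motif
    occurrence of every species, per-species rates, and species names ordered
    by expected divergence.
    """
    rng = np.random.default_rng(spec.seed)
    aas = np.array(list(AMINO_ACIDS))
    ancestor = rng.choice(aas, size=spec.protein_length)
    motif_cols = {}
    for m in spec.motifs:
        for k, c in enumerate(m.consensus):
            ancestor[m.start + k] = c
            motif_cols[m.start + k] = (m, k)

    proteins, cdss = [], []
    truth = {
        "species": [],
        "rates": list(spec.rates),
        "motifs": [
            {"consensus": m.consensus, "start": m.start, "width": len(m.consensus),
             "conservation": m.conservation, "occurrences": {}}
            for m in spec.motifs
        ],
    }
    for si in range(spec.n_species):
        name = f"sp{si:02d}"
        rate = spec.rates[si]
        residues = ancestor.copy()
        for pos in range(spec.protein_length):
            if pos in motif_cols:
                m, _k = motif_cols[pos]
                if rng.random() > m.conservation:
                    choices = [a for a in AMINO_ACIDS if a != ancestor[pos]]
                    residues[pos] = choices[int(rng.integers(19))]
            elif rng.random() < rate:
                choices = [a for a in AMINO_ACIDS if a != ancestor[pos]]
                residues[pos] = choices[int(rng.integers(19))]
        protein = "".join(residues)
        codons = []
        for aa in protein:
            box = _BOX[aa]
            codons.append(
                box[int(rng.integers(len(box)))] if spec.synonymous_wobble else box[0]
            )
        cds = "".join(codons)
        proteins.append(SequenceRecord(name, protein, "protein"))
        cdss.append(SequenceRecord(name, cds, "dna"))
        truth["species"].append(name)
        for mi, m in enumerate(spec.motifs):
            truth["motifs"][mi]["occurrences"][name] = {
                "start": m.start,
                "site": protein[m.start : m.start + len(m.consensus)],
            }
    return proteins, cdss, truth


def demo_family_spec(seed: int = 7, n_species: int = 6) -> FamilySpec:
    """Six-species family with three fully conserved motifs and codon wobble.

    The planted motifs are rich in amino acids with 1- or 2-fold codon boxes
    (M, W, D, E, Y, C, F, N, K, Q, H) — the composition that makes degenerate
    primer design feasible in practice: third-position wobble then yields at
    most 2-fold degeneracy per codon, so 18-22-mer windows stay under the
    64-fold degeneracy cap.  Motif spacings put all three pairwise products in
    the 80-300 bp range on the 600-nt CDS.
    """
    return FamilySpec(
        n_species=n_species,
        protein_length=200,
        rates=[0.3] * n_species,
        motifs=[
            PlantedMotif("MWDEYCFK", 30, 1.0),
            PlantedMotif("WMHQNKECYF", 70, 1.0),
            PlantedMotif("WNDHKM", 120, 1.0),
        ],
        synonymous_wobble=True,
        seed=seed,
    )


@dataclass
class ExprSpec:
    n_genes: int = 40
    n_samples: int = 30
    n_modules: int = 2
    module_size: int = 12
    n_hubs: int = 1
    within_corr: float = 0.8  # target |r| between two same-module genes
    hub_loading: float = 0.9  # hub loading split across module factors
    seed: int = 0

    def __post_init__(self):
        if self.module_size < 3:
            raise ValueError("module size must be >= 3")
        if not 0 < self.within_corr < 1:
            raise ValueError("within-module correlation target must be in (0,1)")
        if self.n_modules * self.module_size + self.n_hubs > self.n_genes:
            raise ValueError("modules + hubs exceed gene count")

    @classmethod
    def from_yaml(cls, path) -> "ExprSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def simulate_expression(spec: ExprSpec):
    """Latent-factor expression matrix with planted modules and hub bridges.

    Module genes load sqrt(within_corr) on their module's factor; hub genes
    load ``hub_loading`` on every module factor (bridging the modules);
    remaining genes are independent noise.  Values are 2^(8 + z), so the
    matrix is positive and log2 transformation recovers the Gaussian scores.
    Returns (genes × samples DataFrame, truth).
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:03d}" for i in range(spec.n_genes)]
    factors = rng.standard_normal((spec.n_modules, spec.n_samples))
    # orthogonalize factor sample vectors against the constant vector and each
    # other, then standardize: the planted module structure (between-module
    # r = 0, stated within-module target) holds in-sample, not just in
    # expectation
    basis = [np.ones(spec.n_samples) / np.sqrt(spec.n_samples)]
    for m in range(spec.n_modules):
        f = factors[m]
        for b in basis:
            f = f - (f @ b) * b
        f = f / f.std()
        basis.append(f / np.linalg.norm(f))
        factors[m] = f - f.mean()
    z = np.zeros((spec.n_genes, spec.n_samples))
    truth = {"modules": {}, "hubs": [], "background": []}
    load = np.sqrt(spec.within_corr)
    noise = np.sqrt(1.0 - spec.within_corr)
    gi = 0
    for m in range(spec.n_modules):
        members = []
        for _ in range(spec.module_size):
            z[gi] = load * factors[m] + noise * rng.standard_normal(spec.n_samples)
            members.append(genes[gi])
            gi += 1
        truth["modules"][f"module{m}"] = members
    # hub variance: (h/sqrt(M))^2 * M + sd^2 = h^2 + sd^2, kept at 1
    hub_noise_sd = np.sqrt(max(1.0 - spec.hub_loading**2, 0.04))
    for _ in range(spec.n_hubs):
        mix = spec.hub_loading / np.sqrt(spec.n_modules) * factors.sum(axis=0)
        z[gi] = mix + hub_noise_sd * rng.standard_normal(spec.n_samples)
        truth["hubs"].append(genes[gi])
        gi += 1
    while gi < spec.n_genes:
        z[gi] = rng.standard_normal(spec.n_samples)
        truth["background"].append(genes[gi])
        gi += 1
    expr = pd.DataFrame(
        np.power(2.0, 8.0 + z),
        index=pd.Index(genes, name="gene"),
        columns=[f"S{j:02d}" for j in range(spec.n_samples)],
    )
    return expr, truth


def simulate_ct(
    fold_changes: pd.DataFrame,
    ref_gene: str = "GAPDH",
    calibrator: str | None = None,
    noise_sd: float = 0.0,
    n_bio_reps: int = 3,
    n_tech_reps: int = 3,
    seed: int = 0,
    ref_ct: float = 20.0,
    gene_base_ct: float = 24.0,
):
    """Ct table generated by inverting the 2^-ddCt formula.

    ``fold_changes`` is genes × tissues (>0); the calibrator (default: first
    column) is forced to fold change 1.  Gaussian noise of ``noise_sd`` cycles
    is added to every Ct measurement.  Returns (Ct DataFrame, truth).
    """
    if (fold_changes.to_numpy() <= 0).any():
        raise ValueError("fold changes must be positive")
    calibrator = calibrator or str(fold_changes.columns[0])
    fc = fold_changes.copy().astype(float)
    fc[calibrator] = 1.0
    rng = np.random.default_rng(seed)
    rows = []
    for tissue in fc.columns:
        for b in range(n_bio_reps):
            for t in range(n_tech_reps):
                rows.append(
                    {"gene": ref_gene, "tissue": tissue, "bio_rep": b,
                     "tech_rep": t, "ct": ref_ct + noise_sd * rng.standard_normal()}
                )
            for gene in fc.index:
                ct0 = gene_base_ct - np.log2(fc.loc[gene, tissue])
                for t in range(n_tech_reps):
                    rows.append(
                        {"gene": gene, "tissue": tissue, "bio_rep": b,
                         "tech_rep": t, "ct": ct0 + noise_sd * rng.standard_normal()}
                    )
    truth = {
        "fold_changes": {g: dict(fc.loc[g]) for g in fc.index},
        "calibrator": calibrator,
        "reference_gene": ref_gene,
    }
    return pd.DataFrame(rows), truth
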