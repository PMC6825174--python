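"""Ungapped protein motif discovery by ZOOPS expectation–maximization.

The model is the one MEME popularised for its "zero or one occurrence per
sequence" (ZOOPS) setting: each sequence either contains no motif site (prior
1 − γ) or exactly one site at a uniformly chosen admissible offset (prior
γ/m).  Site columns are emitted by a width-w position weight matrix (PWM),
all other residues by a fixed background distribution.  EM alternates between
posterior site responsibilities (E) and PWM/γ re-estimation with pseudocounts
(M); the observed-data log-likelihood is non-decreasing.

Sequential discovery of multiple distinct motifs uses the classical
"erasing" trick: sites of an accepted motif are hard-masked before the next
round, so later motifs cannot re-find the same positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
MASK_CHAR = "*"  # residues erased between discovery rounds

_PSEUDOCOUNT = 0.01  # total pseudocount mass added per PWM row, spread by background


@dataclass
class MotifModel:
    """Width-w PWM with background model and ZOOPS occurrence prior."""

    width: int
    pwm: np.ndarray  # (w, 20) rows on the simplex
    background: np.ndarray  # (20,)
    gamma: float  # prior probability a sequence carries one site
    log_likelihood: float = float("-inf")
    ic_bits: float = 0.0
    ll_history: list = field(default_factory=list, repr=False)

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.pwm, axis=1))


@dataclass
class MotifOccurrence:
    seq_id: str
    start: int  # 0-based offset into the protein
    site: str
    posterior: float


@dataclass
class MotifSet:
    """Motifs in discovery order (rank 0 = first/strongest)."""

    motifs: list[tuple[MotifModel, list[MotifOccurrence]]]

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)


def _encode(residues: str) -> np.ndarray:
    """Integer-encode a protein string; X and mask map to -1 (excluded)."""
    return np.array([_AA_INDEX.get(c, -1) for c in residues], dtype=np.int64)


def background_freqs(seqs) -> np.ndarray:
    counts = np.zeros(20)
    for s in seqs:
        enc = _encode(s.residues)
        idx, cnt = np.unique(enc[enc >= 0], return_counts=True)
        counts[idx] += cnt
    if counts.sum() == 0:
        raise ValueError("no countable residues in input")
    counts += 1.0  # Laplace floor so no residue has zero background mass
    return counts / counts.sum()


def information_content(m: MotifModel) -> float:
    """Total PWM information in bits: Σ_rows (log2 20 − H(row))."""
    p = np.clip(m.pwm, 1e-300, 1.0)
    h = -(p * np.log2(p)).sum(axis=1)
    return float((np.log2(20.0) - h).sum())


class _WidthData:
    """Per-width precomputation: window index matrices and validity masks."""

    def __init__(self, seqs, w: int):
        self.ids = [s.id for s in seqs]
        self.windows = []  # list of (m_i, w) int arrays
        self.valid = []  # list of (m_i,) bool arrays; False where window hits X/mask
        self.n_valid = []
        for s in seqs:
            enc = _encode(s.residues)
            if len(enc) < w:
                raise ValueError(f"sequence {s.id!r} shorter than motif width {w}")
            win = sliding_window_view(enc, w)
            ok = (win >= 0).all(axis=1)
            self.windows.append(win)
            self.valid.append(ok)
            self.n_valid.append(int(ok.sum()))


def _seed_pwm(site: str, background: np.ndarray, w: int) -> np.ndarray:
    """PWM initialized from an observed w-mer: 0.7 on the seen residue."""
    pwm = np.full((w, 20), 0.3 / 19.0)
    for k, c in enumerate(site):
        i = _AA_INDEX.get(c)
        if i is None:
            pwm[k] = background
        else:
            pwm[k, :] = 0.3 / 19.0
            pwm[k, i] = 0.7
    return pwm / pwm.sum(axis=1, keepdims=True)


def _em(
    data: _WidthData,
    pwm: np.ndarray,
    background: np.ndarray,
    gamma: float,
    tol: float,
    max_iter: int,
):
    """Run ZOOPS EM to convergence; returns (pwm, gamma, ll, ll_history, posteriors).

    The tracked objective is the MAP-penalized log-likelihood (observed-data
    log-likelihood plus the Dirichlet pseudocount prior on PWM rows); this is
    the quantity EM provably never decreases when M-steps add pseudocounts.
    """
    w = pwm.shape[0]
    log_bg = np.log(background)
    # per-sequence additive constant: background log-prob of countable residues
    # (the encoded sequence is windows[:,0] plus the tail of the last window)
    const = []
    for win in data.windows:
        enc = np.concatenate([win[:, 0], win[-1, 1:]])
        const.append(float(log_bg[enc[enc >= 0]].sum()))

    ll_history: list[float] = []
    prev_ll = -np.inf
    posteriors = None
    for _ in range(max_iter):
        log_pwm = np.log(np.clip(pwm, 1e-300, None))
        log_pwm_ratio = log_pwm - log_bg  # (w, 20)
        prior_term = float((_PSEUDOCOUNT * background * log_pwm).sum())
        counts = _PSEUDOCOUNT * background * np.ones((w, 1))  # β = 0.01·background per row
        gamma_num = 0.0
        ll = 0.0
        posteriors = []
        for win, ok, m_i, c_i in zip(data.windows, data.valid, data.n_valid, const):
            if m_i == 0:
                posteriors.append((np.zeros(len(ok)), 0.0))
                ll += c_i + np.log(max(1.0 - gamma, 1e-300))
                continue
            scores = np.where(
                ok,
                sum(log_pwm_ratio[k][np.clip(win[:, k], 0, 19)] for k in range(w)),
                -np.inf,
            )
            log_site = np.log(max(gamma, 1e-300)) - np.log(m_i) + scores
            log_none = np.log(max(1.0 - gamma, 1e-300))
            mx = max(log_none, float(np.max(log_site)))
            z = np.exp(log_none - mx) + np.exp(log_site - mx).sum()
            log_z = mx + np.log(z)
            post = np.exp(log_site - log_z)  # (m_i,) site responsibilities
            p_site = float(post.sum())
            posteriors.append((post, p_site))
            gamma_num += p_site
            ll += log_z + c_i
            # M-step accumulation
            for k in range(w):
                np.add.at(counts[k], win[ok, k], post[ok])
        ll = ll + prior_term
        ll_history.append(ll)
        gamma = gamma_num / len(data.windows)
        pwm = counts / counts.sum(axis=1, keepdims=True)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return pwm, gamma, ll_history[-1], ll_history, posteriors


def zoops_em(
    seqs,
    w: int,
    seed_site: tuple[str, int] | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    rng_seed: int = 0,
    background: np.ndarray | None = None,
) -> tuple[MotifModel, list[MotifOccurrence]]:
    """Fit one ZOOPS motif of width ``w``.

    ``seed_site`` is a (seq_id, start) pair naming the w-mer used to
    initialize the PWM; if None a w-mer is picked with ``rng_seed``.
    Occurrences are reported for sequences whose posterior probability of
    carrying a site exceeds 0.5, at the argmax offset.
    """
    if not seqs:
        raise ValueError("empty input")
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if background is None:
        background = background_freqs(seqs)
    data = _WidthData(seqs, w)
    by_id = {s.id: s for s in seqs}
    if seed_site is None:
        rng = np.random.default_rng(rng_seed)
        cands = [
            (s.id, j)
            for s, ok in zip(seqs, data.valid)
            for j in np.flatnonzero(ok)
        ]
        if not cands:
            raise ValueError("no unmasked windows available")
        seed_site = cands[int(rng.integers(len(cands)))]
    sid, start = seed_site
    site = by_id[sid].residues[start : start + w]
    pwm0 = _seed_pwm(site, background, w)
    pwm, gamma, ll, hist, posteriors = _em(data, pwm0, background, 0.5, tol, max_iter)
    model = MotifModel(
        width=w,
        pwm=pwm,
        background=background,
        gamma=float(gamma),
        log_likelihood=float(ll),
        ll_history=hist,
    )
    model.ic_bits = information_content(model)
    occs = _occurrences(model, seqs, posteriors)
    return model, occs


def _occurrences(model, seqs, posteriors) -> list[MotifOccurrence]:
    occs = []
    for s, (post, p_site) in zip(seqs, posteriors):
        if p_site > 0.5 and post.size:
            j = int(np.argmax(post))
            occs.append(
                MotifOccurrence(
                    seq_id=s.id,
                    start=j,
                    site=s.residues[j : j + model.width],
                    posterior=float(post[j]),
                )
            )
    return occs


def _enumerate_seeds(data: _WidthData, cap: int) -> list[tuple[str, int]]:
    """Up to ``cap`` evenly spaced valid seed sites across all sequences."""
    all_sites = [
        (sid, int(j))
        for sid, ok in zip(data.ids, data.valid)
        for j in np.flatnonzero(ok)
    ]
    if len(all_sites) <= cap:
        return all_sites
    idx = np.linspace(0, len(all_sites) - 1, cap).astype(int)
    return [all_sites[i] for i in idx]


def discover_motifs(
    seqs,
    n_motifs: int = 20,
    w_min: int = 6,
    w_max: int = 10,
    n_restarts: int = 5,
    rng_seed: int = 0,
    seed_cap: int = 200,
    min_ic_per_col: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> MotifSet:
    """Sequential ZOOPS discovery with erasing.

    For each rank, candidate seeds (observed w-mers, up to ``seed_cap`` evenly
    spaced per width) are screened with two EM iterations; the best
    ``n_restarts`` are run to convergence for every width in
    [w_min, w_max].  The winner across widths maximizes total information
    content penalized by ``min_ic_per_col`` bits per column
    (ic_bits − min_ic_per_col·w), which compares widths on how much
    above-floor signal they capture.  Its occurrence positions are hard-masked
    before the next rank; discovery stops early when the winner's per-column
    information falls below the floor.
    """
    working = [
        SequenceView(s.id, s.residues) for s in seqs
    ]
    background = background_freqs(seqs)
    found: list[tuple[MotifModel, list[MotifOccurrence]]] = []
    for _rank in range(n_motifs):
        best = None  # (criterion, model, occs)
        for w in range(w_min, w_max + 1):
            try:
                data = _WidthData(working, w)
            except ValueError:
                continue
            seeds = _enumerate_seeds(data, seed_cap)
            if not seeds:
                continue
            by_id = {s.id: s for s in working}
            # cheap screen: 2 EM iterations per seed
            screened = []
            for seed in seeds:
                sid, start = seed
                site = by_id[sid].residues[start : start + w]
                pwm0 = _seed_pwm(site, background, w)
                _, _, ll, _, _ = _em(data, pwm0, background, 0.5, tol, 2)
                screened.append((ll, seed))
            screened.sort(key=lambda t: (-t[0], t[1]))
            for _, seed in screened[:n_restarts]:
                model, occs = zoops_em(
                    working, w, seed_site=seed, tol=tol, max_iter=max_iter,
                    background=background,
                )
                crit = model.ic_bits - min_ic_per_col * w
                key = (crit, -w)
                if best is None or key > best[0]:
                    best = (key, model, occs)
        if best is None:
            break
        _, model, occs = best
        if model.ic_bits < min_ic_per_col * model.width:
            break
        found.append((model, occs))
        for occ in occs:  # erase: hard-mask accepted sites
            sv = next(s for s in working if s.id == occ.seq_id)
            sv.mask(occ.start, occ.start + model.width)
    return MotifSet(found)


class SequenceView:
    """Mutable sequence wrapper used during discovery (supports masking)."""

    def __init__(self, id: str, residues: str):
        self.id = id
        self.residues = residues

    def mask(self, start: int, end: int) -> None:
        self.residues = (
            self.residues[:start] + MASK_CHAR * (end - start) + self.residues[end:]
        )

    def __len__(self) -> int:
        return len(self.residues)


def scan(m: MotifModel, seqs, score_threshold: float) -> list[MotifOccurrence]:
    """All sites with log2-odds Σ log2(pwm/background) ≥ threshold.

    Sorted by score descending (ties by sequence id then start).
    """
    lr = np.log2(np.clip(m.pwm, 1e-300, None)) - np.log2(m.background)
    hits = []
    for s in seqs:
        enc = _encode(s.residues)
        if len(enc) < m.width:
            continue
        win = sliding_window_view(enc, m.width)
        ok = (win >= 0).all(axis=1)
        scores = sum(lr[k][np.clip(win[:, k], 0, 19)] for k in range(m.width))
        for j in np.flatnonzero(ok & (scores >= score_threshold)):
            hits.append(
                (
                    -float(scores[j]),
                    s.id,
                    int(j),
                    MotifOccurrence(
                        seq_id=s.id,
                        start=int(j),
                        site=s.residues[j : j + m.width],
                        posterior=float("nan"),
                    ),
                )
            )
    hits.sort(key=lambda t: t[:3])
    return [h[3] for h in hits]
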