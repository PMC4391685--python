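"""Evolutionary distances from alignments.

Nucleotide distances use the observed proportion of differences
(p-distance) and its Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3).
Protein distances are maximum-likelihood estimates under the JTT
(Jones-Taylor-Thornton 1992) empirical substitution model, obtained by
bracketed scalar optimization of the pairwise log-likelihood

    l(d) = sum_sites log( pi_x * P(d)_{xy} ),   P(d) = expm(Q d).

Sites with a gap or ambiguity code in either member of a pair are dropped
for that pair (pairwise deletion, the Phylip default).  Pairs beyond the
model's resolving power are capped at ``d_max`` and flagged saturated so
downstream matrix algebra stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DistanceError
from .io_formats import DNA, PROTEIN, Alignment, DistanceMatrix

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
NUCLEOTIDES = "ACGT"

#: observed p at or beyond which the JC69 correction diverges
JC_SATURATION_P = 0.75


@dataclass(frozen=True)
class DistanceModel:
    """Configuration of a distance estimator.

    name : {"P", "JC69", "JTT"}
    d_max : cap (substitutions/site) assigned to saturated pairs
    tolerance : absolute tolerance of the 1-D ML optimization (JTT only)
    """

    name: str = "JC69"
    d_max: float = 10.0
    gap_policy: str = "pairwise-deletion"
    tolerance: float = 1e-6

    def __post_init__(self):
        if self.name not in ("P", "JC69", "JTT"):
            raise ValueError(f"unknown distance model {self.name!r}")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if self.gap_policy != "pairwise-deletion":
            raise ValueError("only pairwise-deletion gap policy is supported")


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A reversible rate matrix scaled to one expected substitution/unit time."""

    states: str
    Q: np.ndarray
    pi: np.ndarray

    def __post_init__(self):
        k = len(self.states)
        assert self.Q.shape == (k, k)
        assert abs(self.pi.sum() - 1.0) < 1e-10, "frequencies must sum to 1"
        assert np.abs(self.pi @ self.Q).max() < 1e-8, "pi is not stationary for Q"
        off = self.Q[~np.eye(k, dtype=bool)]
        assert np.all(off >= 0), "off-diagonal rates must be non-negative"

    @property
    def _eig(self):
        cached = getattr(self, "_eig_cache", None)
        if cached is None:
            # Q is reversible: S = D^{1/2} Q D^{-1/2} is symmetric (D = diag(pi)),
            # so a stable eigh applies and P(t) = D^{-1/2} V e^{Lt} V' D^{1/2}.
            sq = np.sqrt(self.pi)
            S = (self.Q * sq[:, None]) / sq[None, :]
            lam, V = np.linalg.eigh((S + S.T) / 2.0)
            left = V / sq[:, None]
            rightT = V.T * sq[None, :]
            cached = (lam, left, rightT)
            object.__setattr__(self, "_eig_cache", cached)
        return cached

    def transition_probs(self, d: float) -> np.ndarray:
        """P(d) = expm(Q d), clipped to [0, 1] against round-off."""
        lam, left, rightT = self._eig
        P = (left * np.exp(lam * d)) @ rightT
        return np.clip(P, 0.0, 1.0)


def load_jtt() -> SubstitutionMatrix:
    """Load the bundled JTT exchangeabilities/frequencies as a rate matrix."""
    text = resources.files("phylocongruence.data").joinpath("jtt.txt").read_text()
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    S = np.array([[float(x) for x in ln.split()] for ln in rows[:20]])
    pi = np.array([float(x) for x in rows[20].split()])
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q /= -(pi * np.diag(Q)).sum()  # one expected substitution per unit time
    return SubstitutionMatrix(AMINO_ACIDS, Q, pi)


_JTT = None


def jtt_model() -> SubstitutionMatrix:
    global _JTT
    if _JTT is None:
        _JTT = load_jtt()
    return _JTT


def encode(aln: Alignment) -> np.ndarray:
    """Integer-encode an alignment; gaps and ambiguity codes become -1."""
    states = NUCLEOTIDES if aln.alphabet == DNA else AMINO_ACIDS
    lut = np.full(128, -1, dtype=np.int8)
    for i, ch in enumerate(states):
        lut[ord(ch)] = i
    mat = np.frombuffer("".join(aln.rows).encode(), dtype=np.uint8)
    return lut[mat].reshape(aln.n, aln.length)


def _pair_counts(ci: np.ndarray, cj: np.ndarray, k: int):
    mask = (ci >= 0) & (cj >= 0)
    m = int(mask.sum())
    if m == 0:
        return None, 0
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (ci[mask], cj[mask]), 1)
    return counts, m


def p_distance(aln: Alignment) -> DistanceMatrix:
    """Proportion of differing sites per pair, with pairwise deletion."""
    if aln.n < 2:
        raise DistanceError("need at least 2 sequences")
    codes = encode(aln)
    n = aln.n
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = (codes[i] >= 0) & (codes[j] >= 0)
            m = int(mask.sum())
            if m == 0:
                raise DistanceError(
                    f"no comparable sites between {aln.labels[i]!r} and {aln.labels[j]!r}"
                )
            vals[i, j] = vals[j, i] = np.count_nonzero(
                codes[i][mask] != codes[j][mask]
            ) / m
    return DistanceMatrix(aln.labels, vals)


def jc69(aln: Alignment, model: DistanceModel | None = None) -> DistanceMatrix:
    """Jukes-Cantor distances for a nucleotide alignment.

    Pairs with observed p >= 3/4 are capped at ``model.d_max`` and flagged
    saturated.
    """
    model = model or DistanceModel("JC69")
    if aln.alphabet != DNA:
        raise DistanceError("jc69 requires a DNA alignment")
    P = p_distance(aln).values
    sat = P >= JC_SATURATION_P
    with np.errstate(invalid="ignore"):
        D = -0.75 * np.log1p(-(4.0 / 3.0) * np.where(sat, 0.0, P))
    D[sat] = model.d_max
    np.fill_diagonal(D, 0.0)
    np.fill_diagonal(sat, False)
    return DistanceMatrix(aln.labels, D, sat)


def _jtt_pair_mle(counts: np.ndarray, model: DistanceModel, sm: SubstitutionMatrix):
    """Maximize the pairwise likelihood over d in (0, d_max]."""
    log_pi = np.log(sm.pi)
    sym = counts + counts.T  # likelihood is symmetric in the pair

    def neg_ll(d):
        P = sm.transition_probs(d)
        with np.errstate(divide="ignore"):
            lp = log_pi[:, None] + np.log(P)
        lp[np.isneginf(lp)] = -1e9
        return -0.5 * float((sym * lp).sum())

    off_diagonal = sym.sum() - np.trace(sym)
    if off_diagonal == 0:
        return 0.0, False
    res = minimize_scalar(
        neg_ll,
        bounds=(1e-9, model.d_max),
        method="bounded",
        options={"xatol": model.tolerance},
    )
    d_hat = float(res.x)
    saturated = d_hat >= model.d_max - 10 * model.tolerance
    return (model.d_max if saturated else d_hat), saturated


def jtt_ml_distance(aln: Alignment, model: DistanceModel | None = None) -> DistanceMatrix:
    """Maximum-likelihood pairwise JTT distances for a protein alignment."""
    model = model or DistanceModel("JTT")
    if aln.alphabet != PROTEIN:
        raise DistanceError("jtt_ml_distance requires a protein alignment")
    sm = jtt_model()
    codes = encode(aln)
    n = aln.n
    vals = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            counts, m = _pair_counts(codes[i], codes[j], 20)
            if m == 0:
                raise DistanceError(
                    f"no comparable sites between {aln.labels[i]!r} and {aln.labels[j]!r}"
                )
            d, s = _jtt_pair_mle(counts, model, sm)
            vals[i, j] = vals[j, i] = d
            sat[i, j] = sat[j, i] = s
    return DistanceMatrix(aln.labels, vals, sat)


def compute_distances(aln: Alignment, model: DistanceModel) -> DistanceMatrix:
    """Dispatch on the model name; the entry point the CLI and bootstrap use."""
    if model.name == "P":
        return p_distance(aln)
    if model.name == "JC69":
        return jc69(aln, model)
    return jtt_ml_distance(aln, model)
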