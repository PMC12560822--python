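"""JTT substitution process with gene-specific equilibrium frequencies.

The null model for the convergence scan is a reversible continuous-time
Markov chain on the 20 amino acids.  Exchangeabilities come from the
empirical JTT matrix (Jones, Taylor & Thornton 1992), shipped with the
package as a plain-text file in the standard PAML ``dat`` layout
(lower-triangular exchangeabilities, then the default frequency line).
For each gene the default frequencies are replaced by frequencies counted
from the gene's own alignment ("F_gene"), and the rate matrix is rescaled
so branch lengths are expected substitutions per site.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .io import AMINO_ACIDS, MISSING, Alignment, RifconvError

N_STATES = 20


def load_jtt() -> tuple[np.ndarray, np.ndarray]:
    """Load the packaged JTT exchangeabilities and default frequencies.

    Returns ``(S, pi)`` where ``S`` is the symmetric 20x20 exchangeability
    matrix (zero diagonal) and ``pi`` the published JTT frequencies.
    """
    text = (
        importlib.resources.files("rifconv.data")
        .joinpath("jtt.dat")
        .read_text()
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    S = np.zeros((N_STATES, N_STATES))
    for i in range(1, N_STATES):
        row = [float(v) for v in lines[i - 1].split()]
        S[i, : i] = row
        S[: i, i] = row
    pi = np.array([float(v) for v in lines[N_STATES - 1].split()])
    pi = pi / pi.sum()
    return S, pi


def estimate_f_gene(aln: Alignment, pseudocount: float = 1.0) -> np.ndarray:
    """Gene-specific amino-acid frequencies from observed residue counts.

    Missing cells (gaps, 'X') are excluded; ``pseudocount`` is added to each
    of the 20 states so that with any positive pseudocount every residue
    keeps nonzero equilibrium frequency.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    observed = aln.codes[aln.codes != MISSING]
    if observed.size == 0:
        raise RifconvError(
            f"{aln.gene_id}: alignment entirely missing; no frequencies "
            "estimable"
        )
    counts = np.bincount(observed, minlength=N_STATES).astype(float)
    counts += pseudocount
    return counts / counts.sum()


@dataclass
class SubstitutionModel:
    """Normalized reversible rate matrix Q with its spectral decomposition.

    ``Q[a, b] = s[a, b] * pi[b] / scale`` off-diagonal, diagonal set so rows
    sum to zero, and ``scale`` chosen so the expected rate at equilibrium is
    one substitution per unit branch length.  Reversibility makes Q similar
    to a symmetric matrix through ``diag(sqrt(pi))``; the eigendecomposition
    of that symmetric matrix is cached for fast ``P(t) = expm(Q t)``.
    """

    exchangeabilities: np.ndarray
    pi: np.ndarray
    Q: np.ndarray
    scale: float
    _eigvals: np.ndarray = field(repr=False, default=None)
    _left: np.ndarray = field(repr=False, default=None)
    _right: np.ndarray = field(repr=False, default=None)

    def transition_matrix(self, t: float) -> np.ndarray:
        """Row-stochastic P(t) for a branch of length ``t`` (subst/site)."""
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        # P(t) = D^-1 V exp(L t) V' D with D = diag(sqrt(pi))
        expl = np.exp(self._eigvals * t)
        P = (self._right * expl) @ self._left
        if P.min() < -1e-12:
            raise RifconvError(
                f"transition matrix has negative entry {P.min():.3e} at t={t}"
            )
        np.clip(P, 0.0, None, out=P)
        rows = P.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-8:
            raise RifconvError("transition matrix rows deviate from 1")
        P /= rows[:, None]
        return P


@dataclass
class TransitionMatrix:
    t: float
    P: np.ndarray


def build_model(pi: np.ndarray,
                exchangeabilities: np.ndarray | None = None) -> SubstitutionModel:
    """Assemble the normalized JTT+F rate matrix for frequency vector ``pi``."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_STATES,):
        raise ValueError(f"pi must have shape (20,), got {pi.shape}")
    if np.any(pi <= 0):
        bad = [AMINO_ACIDS[i] for i in np.where(pi <= 0)[0]]
        raise RifconvError(
            f"nonpositive equilibrium frequency for {','.join(bad)}; "
            "use a positive pseudocount upstream"
        )
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("pi must sum to 1")
    pi = pi / pi.sum()
    if exchangeabilities is None:
        exchangeabilities = _JTT_S
    S = np.asarray(exchangeabilities, dtype=float)
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    if scale <= 0:
        raise RifconvError("degenerate rate matrix (zero total rate)")
    Q = Q / scale
    model = SubstitutionModel(exchangeabilities=S, pi=pi, Q=Q, scale=scale)
    sqrt_pi = np.sqrt(pi)
    sym = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
    sym = 0.5 * (sym + sym.T)  # symmetrize away rounding
    eigvals, V = np.linalg.eigh(sym)
    model._eigvals = eigvals
    model._right = V / sqrt_pi[:, None]       # D^-1 V
    model._left = V.T * sqrt_pi[None, :]      # V' D
    return model


def transition_probabilities(model: SubstitutionModel, t: float) -> TransitionMatrix:
    """Transition probabilities over a branch of length ``t``."""
    return TransitionMatrix(t=t, P=model.transition_matrix(t))


_JTT_S, JTT_FREQUENCIES = load_jtt()
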