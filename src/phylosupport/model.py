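"""Substitution models: LG exchangeabilities, +F frequencies, discrete-gamma
rate variation, and finite profile mixtures (CAT/C60-style site heterogeneity).

A :class:`SubstitutionModel` couples one symmetric exchangeability matrix with
``K`` equilibrium-frequency profiles and weights.  ``K = 1`` is the classical
site-homogeneous +F model; larger ``K`` gives each site a latent frequency
profile, the finite-mixture analogue of the CAT and C60 models.  Every profile
defines a reversible rate matrix Q_ij = s_ij * pi_j, calibrated so the
expected substitution rate at stationarity is 1, keeping branch lengths in
expected substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .alphabet import AA_ORDER, N_STATES
from .lg import LG_FREQS, lg_exchangeabilities


class ModelError(ValueError):
    """Invalid substitution-model parameter."""


def discretize_gamma(alpha: float, k: int) -> np.ndarray:
    """Equal-weight discrete-gamma category rates (mean-of-category scheme).

    The Gamma(alpha, 1/alpha) density (mean 1) is cut at its ``i/k`` quantiles
    and each category is represented by its conditional mean, computed from
    the regularized incomplete gamma function.  The returned rates are
    renormalized so their mean is exactly 1 and are nondecreasing.
    """
    if not alpha > 0:
        raise ModelError(f"gamma shape must be positive, got {alpha}")
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ModelError(f"category count must be an integer >= 1, got {k}")
    if k == 1:
        return np.ones(1)
    # quantile boundaries of Gamma(shape=alpha, scale=1/alpha)
    probs = np.arange(1, k) / k
    bounds = special.gammaincinv(alpha, probs) / alpha
    # mean within each bin: k * [I(alpha+1, b*alpha) - I(alpha+1, a*alpha)]
    cdf1 = np.concatenate([[0.0], special.gammainc(alpha + 1, bounds * alpha), [1.0]])
    rates = k * np.diff(cdf1)
    rates = np.maximum(rates, 1e-12)
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """Reversible amino-acid model: exchangeabilities x frequency profiles.

    Parameters
    ----------
    exchangeabilities:
        Symmetric nonnegative 20x20 matrix, zero diagonal (default LG).
    profiles:
        (K, 20) row-stochastic matrix of equilibrium frequency profiles.
    profile_weights:
        Length-K simplex vector of mixture weights.
    gamma_alpha:
        Shape of discrete-gamma among-site rate variation, or None for a
        single rate class.
    n_rate_categories:
        Number of equal-weight gamma categories (ignored when
        ``gamma_alpha`` is None).
    """

    exchangeabilities: np.ndarray = field(default_factory=lg_exchangeabilities)
    profiles: np.ndarray = field(default_factory=lambda: LG_FREQS[None, :].copy())
    profile_weights: np.ndarray | None = None
    gamma_alpha: float | None = None
    n_rate_categories: int = 4
    name: str = ""

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.profiles = np.atleast_2d(np.asarray(self.profiles, dtype=float))
        if self.profile_weights is None:
            self.profile_weights = np.full(self.n_profiles, 1.0 / self.n_profiles)
        self.profile_weights = np.asarray(self.profile_weights, dtype=float)
        self._validate()

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        s = self.exchangeabilities
        if s.shape != (N_STATES, N_STATES):
            raise ModelError(f"exchangeability matrix must be 20x20, got {s.shape}")
        if not np.allclose(s, s.T):
            raise ModelError("exchangeability matrix must be symmetric")
        if (s < 0).any() or np.abs(np.diag(s)).max() > 0:
            raise ModelError("exchangeabilities must be nonnegative with zero diagonal")
        if self.profiles.shape[1] != N_STATES:
            raise ModelError(f"profiles must have 20 columns, got {self.profiles.shape}")
        if (self.profiles <= 0).any():
            raise ModelError("profile frequencies must be strictly positive")
        if not np.allclose(self.profiles.sum(axis=1), 1.0, atol=1e-12):
            raise ModelError("each profile row must sum to 1 (within 1e-12)")
        w = self.profile_weights
        if w.shape != (self.n_profiles,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
            raise ModelError("profile weights must lie on the K-simplex")
        if self.gamma_alpha is not None and not self.gamma_alpha > 0:
            raise ModelError(f"gamma shape must be positive, got {self.gamma_alpha}")
        if self.n_rate_categories < 1:
            raise ModelError("need at least one rate category")

    # -- derived quantities -------------------------------------------------
    @property
    def n_profiles(self) -> int:
        return self.profiles.shape[0]

    def category_rates(self) -> np.ndarray:
        """Relative rates of the gamma categories ([1.0] when no gamma)."""
        if self.gamma_alpha is None:
            return np.ones(1)
        return discretize_gamma(self.gamma_alpha, self.n_rate_categories)

    def rate_matrix(self, profile_index: int = 0) -> np.ndarray:
        """Calibrated rate matrix for one profile (expected rate 1)."""
        pi = self.profiles[profile_index]
        q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def spectral(self) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-profile symmetric eigendecomposition of the rate matrix.

        Returns for each profile ``(lam, left, right)`` with
        ``P(t) = right @ diag(exp(lam*t)) @ left`` and, conveniently for
        edge-likelihood evaluation, ``diag(pi) @ P(t) = left.T @ diag(exp(lam*t)) @ left``.
        """
        out = []
        for k in range(self.n_profiles):
            pi = self.profiles[k]
            q = self.rate_matrix(k)
            sq = np.sqrt(pi)
            sym = sq[:, None] * q / sq[None, :]
            lam, u = np.linalg.eigh((sym + sym.T) / 2)
            left = u.T * sq[None, :]          # U^T S
            right = (1.0 / sq)[:, None] * u   # S^-1 U
            out.append((lam, left, right))
        return out

    def with_(self, **changes) -> "SubstitutionModel":
        """Copy with selected fields replaced."""
        kw = dict(
            exchangeabilities=self.exchangeabilities,
            profiles=self.profiles,
            profile_weights=self.profile_weights,
            gamma_alpha=self.gamma_alpha,
            n_rate_categories=self.n_rate_categories,
            name=self.name,
        )
        kw.update(changes)
        return SubstitutionModel(**kw)

    # -- constructors -------------------------------------------------------
    @classmethod
    def lg(cls, gamma_alpha: float | None = None, n_rate_categories: int = 4,
           frequencies: np.ndarray | None = None) -> "SubstitutionModel":
        """Site-homogeneous LG model, optionally +F frequencies and +G rates."""
        freqs = LG_FREQS if frequencies is None else np.asarray(frequencies, float)
        return cls(profiles=freqs[None, :], gamma_alpha=gamma_alpha,
                   n_rate_categories=n_rate_categories,
                   name="LG+G" if gamma_alpha else "LG")

    @classmethod
    def mixture(cls, profiles: np.ndarray, weights: np.ndarray | None = None,
                gamma_alpha: float | None = None, n_rate_categories: int = 4,
                ) -> "SubstitutionModel":
        """Profile-mixture model with LG exchangeabilities."""
        return cls(profiles=profiles, profile_weights=weights,
                   gamma_alpha=gamma_alpha, n_rate_categories=n_rate_categories,
                   name="MIX+LG+G" if gamma_alpha else "MIX+LG")


def observed_frequencies(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """+F frequencies from residue counts with an additive pseudocount."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (N_STATES,):
        raise ModelError(f"expected 20 residue counts, got shape {counts.shape}")
    freqs = counts + pseudocount
    return freqs / freqs.sum()


def read_profile_library(path) -> np.ndarray:
    """Read a K x 20 profile library from TSV (header = residue letters)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = [c.strip().upper() for c in df.columns]
    if cols != list(AA_ORDER):
        raise ModelError(
            f"profile library header must be the residues {' '.join(AA_ORDER)}")
    profiles = df.to_numpy(dtype=float)
    return profiles / profiles.sum(axis=1, keepdims=True)


def write_profile_library(path, profiles: np.ndarray) -> None:
    """Write a K x 20 profile library as TSV with residue-letter header."""
    import pandas as pd

    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    pd.DataFrame(profiles, columns=list(AA_ORDER)).to_csv(
        path, sep="\t", index=False, float_format="%.10g")
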