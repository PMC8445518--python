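"""Double-Gaussian mixture coincidence timing kernels.

A BGO-Cherenkov detector pair does not have a single coincidence timing
resolution.  Depending on how many prompt Cherenkov photons were detected
on either side, the coincidence time-difference distribution of an event
class is well described by a zero-mean two-component Gaussian mixture: a
narrow "fast" component (Cherenkov-rich events) and a wide "slow"
component (scintillation-only events), mixed with an abundance weight
``alpha_fast``.  Pairing five rise-time classes per detector yields 25
such timing categories; the packaged bank carries their fast/slow FWHM
and abundance values.

This module represents those kernels, evaluates their density and CDF,
samples coincidence time differences from them, refits mixtures to
samples by expectation-maximization, and validates that the sampled
distributions reproduce the input kernel parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "FWHM_PER_SIGMA",
    "GaussianComponent",
    "MixtureTimingKernel",
    "KernelBank",
    "MixtureFitResult",
    "load_bgo_cherenkov_bank",
    "load_bank",
    "save_bank",
    "mixture_pdf",
    "mixture_cdf",
    "sample_delta_t",
    "mixture_fwhm",
    "fit_two_gaussian_mixture",
    "validate_bank_fidelity",
]

#: FWHM of a Gaussian in units of its standard deviation, 2*sqrt(2*ln 2).
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

_DATA_PACKAGE = "tofmix.data"
_BANK_FILENAME = "bgo_cherenkov_kernels.tsv"


@dataclass(frozen=True)
class GaussianComponent:
    """One zero-mean Gaussian mixture component, parameterized by FWHM in ps."""

    fwhm_ps: float

    def __post_init__(self) -> None:
        if not self.fwhm_ps > 0:
            raise ValueError(f"fwhm_ps must be positive, got {self.fwhm_ps}")

    @property
    def sigma_ps(self) -> float:
        return self.fwhm_ps / FWHM_PER_SIGMA

    @classmethod
    def from_sigma(cls, sigma_ps: float) -> "GaussianComponent":
        return cls(fwhm_ps=sigma_ps * FWHM_PER_SIGMA)


@dataclass(frozen=True)
class MixtureTimingKernel:
    """A zero-mean two-component Gaussian coincidence-timing kernel.

    ``alpha_fast`` is the abundance of the fast component: the probability
    that a coincidence of this timing category drew its time spread from
    the narrow Gaussian.  ``kernel_id`` 1..25 refers to the packaged
    timing-category bank; 0 is used for fitted or ad-hoc kernels.
    """

    kernel_id: int
    fast: GaussianComponent
    slow: GaussianComponent
    alpha_fast: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_fast <= 1.0:
            raise ValueError(f"alpha_fast must be in [0, 1], got {self.alpha_fast}")
        if self.kernel_id < 0:
            raise ValueError("kernel_id must be nonnegative")
        if self.fast.fwhm_ps > self.slow.fwhm_ps:
            warnings.warn(
                f"kernel {self.kernel_id}: fast FWHM {self.fast.fwhm_ps} ps exceeds "
                f"slow FWHM {self.slow.fwhm_ps} ps; component labels look swapped",
                stacklevel=2,
            )

    @property
    def sigma_fast_ps(self) -> float:
        return self.fast.sigma_ps

    @property
    def sigma_slow_ps(self) -> float:
        return self.slow.sigma_ps


@dataclass(frozen=True)
class KernelBank:
    """An ordered collection of timing kernels with category probabilities.

    ``category_probs[k]`` is the probability that a coincidence is assigned
    timing category ``kernels[k]``; the default is uniform.
    """

    kernels: tuple[MixtureTimingKernel, ...]
    category_probs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        kernels = tuple(self.kernels)
        object.__setattr__(self, "kernels", kernels)
        if self.category_probs is None:
            probs = np.full(len(kernels), 1.0 / len(kernels))
        else:
            probs = np.asarray(self.category_probs, dtype=float)
        if probs.shape != (len(kernels),):
            raise ValueError("category_probs length must match number of kernels")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("category_probs must be nonnegative and sum to 1")
        object.__setattr__(self, "category_probs", probs)

    def __len__(self) -> int:
        return len(self.kernels)

    def __getitem__(self, index: int) -> MixtureTimingKernel:
        return self.kernels[index]

    def get(self, kernel_id: int) -> MixtureTimingKernel:
        """Look a kernel up by its id (not list position)."""
        for k in self.kernels:
            if k.kernel_id == kernel_id:
                return k
        raise KeyError(f"no kernel with id {kernel_id} in bank")

    def sigma_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(sigma_fast, sigma_slow, alpha_fast) indexed by kernel_id (0 unused)."""
        max_id = max(k.kernel_id for k in self.kernels)
        sig_f = np.zeros(max_id + 1)
        sig_s = np.zeros(max_id + 1)
        alpha = np.zeros(max_id + 1)
        for k in self.kernels:
            sig_f[k.kernel_id] = k.sigma_fast_ps
            sig_s[k.kernel_id] = k.sigma_slow_ps
            alpha[k.kernel_id] = k.alpha_fast
        return sig_f, sig_s, alpha


def _bank_from_frame(df: pd.DataFrame, source: str) -> KernelBank:
    required = ["kernel_id", "fwhm_fast_ps", "fwhm_slow_ps", "alpha_fast"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"kernel bank {source}: missing columns {missing}")
    kernels = []
    for _, row in df.iterrows():
        try:
            kid = int(row["kernel_id"])
            fast = GaussianComponent(float(row["fwhm_fast_ps"]))
            slow = GaussianComponent(float(row["fwhm_slow_ps"]))
            alpha = float(row["alpha_fast"])
            if fast.fwhm_ps > slow.fwhm_ps:
                raise ValueError("fast FWHM exceeds slow FWHM")
            kernels.append(
                MixtureTimingKernel(kernel_id=kid, fast=fast, slow=slow, alpha_fast=alpha)
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"kernel bank {source}: malformed row kernel_id={row['kernel_id']}: {exc}"
            ) from exc
    return KernelBank(kernels=tuple(kernels))


def load_bank(path) -> KernelBank:
    """Load a kernel bank from a tab- or comma-delimited file with a header."""
    df = pd.read_csv(path, sep=None, engine="python")
    return _bank_from_frame(df, str(path))


def save_bank(bank: KernelBank, path, sep: str = "\t") -> None:
    rows = [
        {
            "kernel_id": k.kernel_id,
            "fwhm_fast_ps": k.fast.fwhm_ps,
            "fwhm_slow_ps": k.slow.fwhm_ps,
            "alpha_fast": k.alpha_fast,
        }
        for k in bank.kernels
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def load_bgo_cherenkov_bank() -> KernelBank:
    """Load the packaged bank of 25 BGO-Cherenkov timing categories.

    Category probabilities are uniform (each rise-time class holds an equal
    share of the photopeak events, so the 25 pairings are equiprobable).
    """
    with resources.files(_DATA_PACKAGE).joinpath(_BANK_FILENAME).open("r") as fh:
        df = pd.read_csv(fh, sep="\t")
    bank = _bank_from_frame(df, _BANK_FILENAME)
    if len(bank) != 25:
        raise ValueError(f"packaged bank must have 25 kernels, found {len(bank)}")
    return bank


def mixture_pdf(kernel: MixtureTimingKernel, t_ps) -> np.ndarray | float:
    """Mixture probability density (per ps) at time difference ``t_ps``."""
    t = np.asarray(t_ps, dtype=float)
    sf, ss = kernel.sigma_fast_ps, kernel.sigma_slow_ps
    a = kernel.alpha_fast
    out = a * np.exp(-0.5 * (t / sf) ** 2) / (sf * math.sqrt(2 * math.pi)) + (
        1 - a
    ) * np.exp(-0.5 * (t / ss) ** 2) / (ss * math.sqrt(2 * math.pi))
    return out if out.ndim else float(out)


def mixture_cdf(kernel: MixtureTimingKernel, t_ps) -> np.ndarray | float:
    """Mixture cumulative distribution at time difference ``t_ps``."""
    t = np.asarray(t_ps, dtype=float)
    a = kernel.alpha_fast
    out = a * special.ndtr(t / kernel.sigma_fast_ps) + (1 - a) * special.ndtr(
        t / kernel.sigma_slow_ps
    )
    return out if out.ndim else float(out)


def sample_delta_t(
    kernel: MixtureTimingKernel, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` coincidence time differences from a mixture kernel.

    Each draw first selects fast vs. slow with probability ``alpha_fast``,
    then draws a zero-mean Gaussian with the selected component's sigma;
    this mirrors how the simulator applies timing spreads per coincidence.

    Returns ``(delta_t_ps, is_fast)`` where ``is_fast`` is a boolean array
    recording the component actually applied to each draw.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    is_fast = rng.random(n) < kernel.alpha_fast
    sigma = np.where(is_fast, kernel.sigma_fast_ps, kernel.sigma_slow_ps)
    return rng.standard_normal(n) * sigma, is_fast


def mixture_fwhm(kernel: MixtureTimingKernel) -> float:
    """Full width at half maximum of the mixture density, in ps.

    A zero-mean scale mixture of Gaussians peaks at 0 and decreases
    monotonically in |t|, so the half-maximum crossing is bracketed and
    found by root finding.
    """
    peak = mixture_pdf(kernel, 0.0)
    target = 0.5 * peak
    hi = 4.0 * kernel.sigma_slow_ps
    while mixture_pdf(kernel, hi) > target:  # pragma: no cover - defensive
        hi *= 2.0
    root = optimize.brentq(lambda t: mixture_pdf(kernel, t) - target, 0.0, hi, xtol=1e-9)
    return 2.0 * root


@dataclass(frozen=True)
class MixtureFitResult:
    kernel: MixtureTimingKernel
    log_likelihood: float
    n_iter: int
    converged: bool
    log_likelihood_path: np.ndarray


def fit_two_gaussian_mixture(
    samples: Sequence[float] | np.ndarray,
    init: MixtureTimingKernel | None = None,
    max_iter: int = 500,
    tol_per_event: float = 1e-8,
) -> MixtureFitResult:
    """Maximum-likelihood zero-mean two-component Gaussian mixture fit (EM).

    Both component means are constrained to zero, matching centered timing
    kernels; the free parameters are the two sigmas and the mixing weight.
    The component with the smaller fitted sigma is reported as "fast".
    EM iterates until the mean log-likelihood improves by less than
    ``tol_per_event`` or ``max_iter`` is reached; the log-likelihood is
    nondecreasing by construction.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("need at least 4 samples to fit a two-component mixture")
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate samples (all equal); mixture fit undefined")
    x2 = x * x
    n = x.size

    if init is not None:
        sig = np.array([init.sigma_fast_ps, init.sigma_slow_ps], dtype=float)
        alpha = float(init.alpha_fast)
    else:
        # method-of-moments style split around the sample SD
        sig = np.array([0.5 * sd, 2.0 * sd])
        alpha = 0.5

    log_2pi = math.log(2 * math.pi)
    ll_path = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step: responsibilities of the first (nominally fast) component
        log_pf = -0.5 * x2 / sig[0] ** 2 - math.log(sig[0]) - 0.5 * log_2pi
        log_ps = -0.5 * x2 / sig[1] ** 2 - math.log(sig[1]) - 0.5 * log_2pi
        la = math.log(max(alpha, 1e-300))
        lb = math.log(max(1 - alpha, 1e-300))
        log_num_f = la + log_pf
        log_num_s = lb + log_ps
        log_norm = np.logaddexp(log_num_f, log_num_s)
        ll = float(log_norm.sum())
        ll_path.append(ll)
        if ll - ll_prev < tol_per_event * n and it > 1:
            converged = True
            break
        ll_prev = ll
        r = np.exp(log_num_f - log_norm)
        # M step: zero-mean variance updates
        rsum = r.sum()
        if rsum < 1e-12 or n - rsum < 1e-12:
            # one component vanished; collapse to a single Gaussian
            alpha = min(max(rsum / n, 0.0), 1.0)
            s_all = math.sqrt(float(x2.mean()))
            sig = np.array([s_all, s_all])
            converged = True
            break
        alpha = rsum / n
        sig[0] = math.sqrt(float((r * x2).sum() / rsum))
        sig[1] = math.sqrt(float(((1 - r) * x2).sum() / (n - rsum)))
        sig = np.maximum(sig, 1e-12)

    if sig[0] <= sig[1]:
        sig_f, sig_s, a_f = sig[0], sig[1], alpha
    else:
        sig_f, sig_s, a_f = sig[1], sig[0], 1 - alpha
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitted = MixtureTimingKernel(
            kernel_id=0,
            fast=GaussianComponent.from_sigma(float(sig_f)),
            slow=GaussianComponent.from_sigma(float(sig_s)),
            alpha_fast=float(np.clip(a_f, 0.0, 1.0)),
        )
    return MixtureFitResult(
        kernel=fitted,
        log_likelihood=ll_path[-1],
        n_iter=it,
        converged=converged,
        log_likelihood_path=np.asarray(ll_path),
    )


def validate_bank_fidelity(
    bank: KernelBank, n_per_kernel: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Sample-and-refit fidelity check for every kernel in a bank.

    For each kernel, ``n_per_kernel`` time differences are drawn and the
    zero-mean mixture is refit by EM; the table reports input vs. fitted
    sigmas and abundance with absolute errors.  At 10^6 draws per kernel
    the sigma errors stay within a couple of ps, which is the statistical
    fidelity level of the simulation itself.
    """
    if n_per_kernel < 1:
        raise ValueError("n_per_kernel must be >= 1")
    rows = []
    for kernel in bank.kernels:
        dt, _ = sample_delta_t(kernel, n_per_kernel, rng)
        fit = fit_two_gaussian_mixture(dt)
        fk = fit.kernel
        rows.append(
            {
                "kernel_id": kernel.kernel_id,
                "sigma_fast_in_ps": kernel.sigma_fast_ps,
                "sigma_fast_fit_ps": fk.sigma_fast_ps,
                "sigma_slow_in_ps": kernel.sigma_slow_ps,
                "sigma_slow_fit_ps": fk.sigma_slow_ps,
                "alpha_in": kernel.alpha_fast,
                "alpha_fit": fk.alpha_fast,
                "abs_err_sigma_fast_ps": abs(fk.sigma_fast_ps - kernel.sigma_fast_ps),
                "abs_err_sigma_slow_ps": abs(fk.sigma_slow_ps - kernel.sigma_slow_ps),
                "abs_err_alpha": abs(fk.alpha_fast - kernel.alpha_fast),
                "n_samples": n_per_kernel,
                "em_iterations": fit.n_iter,
                "em_converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
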