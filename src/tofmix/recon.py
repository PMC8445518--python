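"""List-mode TOF MLEM reconstruction with mixture timing kernels.

The image update is the classic list-mode EM step

    lambda_j  <-  (lambda_j / s_j) * sum_i  p_ij K_ij / sum_k p_ik K_ik lambda_k

where ``p_ij`` is the geometric intersection length of event *i*'s line
of response with voxel *j* (Siddon ray tracing) and ``K_ij`` is the TOF
weight: the difference of the event's timing-kernel CDF across the TOF
bin holding the measured time difference, evaluated at the voxel
center's projection onto the LOR time axis.  For a mixture kernel

    K = (1 - a) [cdf_S(k2 - v') - cdf_S(k1 - v')] + a [cdf_F(k2 - v') - cdf_F(k1 - v')]

with ``a`` the fast-component abundance.  Because the TOF weights over
all bins telescope to one, the sensitivity image ``s_j`` is TOF-free:
the sum of ``p_ij`` (times attenuation survival) over every admissible
detector pair.

Five weighting modes are supported: per-event mixture kernels from a
bank (``mixture_bank``), one fixed mixture kernel (``single_mixture``),
the decomposed variant that uses the exact single Gaussian component
recorded for each event (``decomposed``), a plain single Gaussian
(``single_gaussian``), and ``non_tof``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tracing import C_MM_PER_PS, mlem_pass, sensitivity_pass, trace_ray
from .geometry import RingScanner, VoxelGrid, crystal_centers
from .kernels import FWHM_PER_SIGMA, KernelBank, MixtureTimingKernel, mixture_cdf
from .listmode import COMP_FAST, COMP_NA, COMP_SLOW, ListModeData

__all__ = [
    "TOFBinning",
    "ReconModel",
    "ReconConfig",
    "ReconResult",
    "siddon_path",
    "voxel_tof_projection",
    "tof_weight",
    "sensitivity_image",
    "lm_mlem",
    "calibrate",
]

#: Voxels farther than this many slow-component sigmas from the measured
#: time difference are dropped from the TOF weighting (mass < ~2e-9).
TOF_TRUNCATION_NSIGMA = 6.0


@dataclass(frozen=True)
class TOFBinning:
    """Uniform TOF binning; bin t covers [t*width, (t+1)*width) ps."""

    bin_width_ps: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_width_ps <= 0:
            raise ValueError("bin width must be positive")

    def bin_edges(self, delta_t_ps: float) -> tuple[float, float]:
        """Edges of the bin containing ``delta_t_ps``."""
        w = self.bin_width_ps
        k1 = np.floor(delta_t_ps / w) * w
        return float(k1), float(k1 + w)

    def edges_covering(self, t_lo_ps: float, t_hi_ps: float) -> np.ndarray:
        """Contiguous edges of all bins overlapping [t_lo, t_hi]."""
        w = self.bin_width_ps
        k0 = np.floor(t_lo_ps / w)
        k1 = np.ceil(t_hi_ps / w)
        return np.arange(k0, k1 + 1) * w


@dataclass(frozen=True)
class ReconModel:
    mode: str
    bank: KernelBank | None = None
    fwhm_ps: float | None = None
    kernel_id: int = 1

    _MODES = ("mixture_bank", "single_mixture", "decomposed", "single_gaussian", "non_tof")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown recon mode {self.mode!r}; expected {self._MODES}")
        if self.mode in ("mixture_bank", "single_mixture", "decomposed") and self.bank is None:
            raise ValueError(f"mode {self.mode!r} requires a kernel bank")
        if self.mode == "single_gaussian" and not (self.fwhm_ps and self.fwhm_ps > 0):
            raise ValueError("single_gaussian mode requires a positive fwhm_ps")

    def event_kernel_params(
        self, events: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
        """Per-event ``(sigma_fast, sigma_slow, alpha_fast, tof_on)``.

        Non-mixture kernels are expressed as a degenerate mixture with
        ``alpha = 1`` so one weighting routine serves every mode.
        """
        n = len(events)
        if self.mode == "non_tof":
            z = np.zeros(n)
            return z, z, z, False
        if self.mode == "single_gaussian":
            s = np.full(n, self.fwhm_ps / FWHM_PER_SIGMA)
            return s, s.copy(), np.ones(n), True
        sig_f, sig_s, alpha = self.bank.sigma_arrays()
        if self.mode == "single_mixture":
            k = self.bank.get(self.kernel_id)
            return (
                np.full(n, k.sigma_fast_ps),
                np.full(n, k.sigma_slow_ps),
                np.full(n, k.alpha_fast),
                True,
            )
        kids = events["kernel_id"].astype(np.int64)
        if np.any(kids == 0) or np.any(kids >= sig_f.size):
            raise ValueError(
                f"mode {self.mode!r} needs per-event kernel ids matching the bank"
            )
        if self.mode == "mixture_bank":
            return sig_f[kids], sig_s[kids], alpha[kids], True
        # decomposed: the exact component applied during simulation
        comp = events["component_flag"]
        if np.any(comp == COMP_NA):
            raise ValueError("decomposed mode requires per-event component flags")
        sigma = np.where(comp == COMP_FAST, sig_f[kids], sig_s[kids])
        return sigma, sigma.copy(), np.ones(n), True


@dataclass(frozen=True)
class ReconConfig:
    grid: VoxelGrid
    model: ReconModel
    n_iterations: int = 40
    tof_binning: TOFBinning = field(default_factory=TOFBinning)
    attenuation_image: np.ndarray | None = None
    save_every: int | None = None
    save_iterations: tuple[int, ...] = ()
    sensitivity: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class ReconResult:
    image: np.ndarray
    snapshots: dict[int, np.ndarray]
    log_likelihood: np.ndarray
    conservation_residual: np.ndarray
    n_events_used: int
    n_events_skipped: int
    sensitivity: np.ndarray


def siddon_path(
    grid: VoxelGrid, p1: np.ndarray, p2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Voxels crossed by the segment p1 -> p2 and their intersection lengths.

    Returns ``(indices, lengths_mm)`` with ``indices`` of shape (n, 3);
    the lengths sum to the in-grid chord length.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.array_equal(p1, p2):
        raise ValueError("degenerate ray: endpoints coincide")
    cap = grid.nx + grid.ny + grid.nz + 4
    idx = np.empty(cap, dtype=np.int64)
    seg = np.empty(cap)
    ox, oy, oz = grid.origin_mm
    vx, vy, vz = grid.voxel_size_mm
    n = trace_ray(
        p1[0], p1[1], p1[2], p2[0], p2[1], p2[2],
        ox, oy, oz, vx, vy, vz, grid.nx, grid.ny, grid.nz, idx, seg,
    )
    n = max(n, 0)
    flat = idx[:n]
    iz = flat % grid.nz
    iy = (flat // grid.nz) % grid.ny
    ix = flat // (grid.nz * grid.ny)
    return np.column_stack([ix, iy, iz]), seg[:n].copy()


def voxel_tof_projection(
    grid: VoxelGrid, voxel_index: tuple[int, int, int], p1: np.ndarray, p2: np.ndarray
) -> float:
    """Signed TOF coordinate (ps) of a voxel center along the LOR p1 -> p2.

    The voxel center is projected orthogonally onto the LOR axis; the
    result is ``2 (s - s_mid) / c``, positive toward ``p2``, matching the
    simulator's time-difference sign convention.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    center = grid.voxel_center(*voxel_index)
    axis = p2 - p1
    axis = axis / np.linalg.norm(axis)
    s = float((center - 0.5 * (p1 + p2)) @ axis)
    return 2.0 * s / C_MM_PER_PS


def tof_weight(
    model: ReconModel,
    event: np.ndarray,
    v_cj_ps: float,
    binning: TOFBinning,
    bin_edges: tuple[float, float] | None = None,
) -> float:
    """TOF weight of one voxel for one event: the event kernel's CDF mass
    on the TOF bin containing the measured time difference, centered on
    the voxel's LOR-time coordinate ``v_cj_ps``."""
    if model.mode == "non_tof":
        return 1.0
    if bin_edges is None:
        bin_edges = binning.bin_edges(float(event["delta_t_ps"]))
    k1, k2 = bin_edges
    sig_f, sig_s, alpha, _ = model.event_kernel_params(
        np.atleast_1d(np.asarray(event))
    )
    from .kernels import GaussianComponent

    kernel = MixtureTimingKernel(
        kernel_id=0,
        fast=GaussianComponent.from_sigma(float(sig_f[0])),
        slow=GaussianComponent.from_sigma(float(sig_s[0])),
        alpha_fast=float(alpha[0]),
    )
    return float(mixture_cdf(kernel, k2 - v_cj_ps) - mixture_cdf(kernel, k1 - v_cj_ps))


def sensitivity_image(
    scanner: RingScanner,
    grid: VoxelGrid,
    attenuation_image: np.ndarray | None = None,
    min_sector_difference: int | None = None,
) -> np.ndarray:
    """Per-voxel sensitivity: total intersection length over all
    admissible detector pairs, times attenuation survival when given.

    TOF weights sum out over bins, so the sensitivity is independent of
    the timing model.
    """
    from .simulate import default_min_sector_difference

    if min_sector_difference is None:
        min_sector_difference = default_min_sector_difference(scanner)
    centers = crystal_centers(scanner)
    crystal_index = (np.arange(scanner.n_detectors) % scanner.n_crystals_per_ring).astype(
        np.int64
    )
    ox, oy, oz = grid.origin_mm
    vx, vy, vz = grid.voxel_size_mm
    if attenuation_image is not None:
        mu_flat = np.ascontiguousarray(attenuation_image, dtype=float).ravel()
        use_atten = True
    else:
        mu_flat = np.zeros(1)
        use_atten = False
    s = sensitivity_pass(
        np.ascontiguousarray(centers[:, 0]),
        np.ascontiguousarray(centers[:, 1]),
        np.ascontiguousarray(centers[:, 2]),
        crystal_index,
        scanner.n_crystals_per_ring,
        min_sector_difference,
        ox, oy, oz, vx, vy, vz, grid.nx, grid.ny, grid.nz,
        mu_flat, use_atten,
    )
    return s.reshape(grid.shape)


def lm_mlem(data: ListModeData, config: ReconConfig) -> ReconResult:
    """Run list-mode MLEM for ``config.n_iterations`` full passes.

    The initial image is 1 inside the sensitivity support and 0 outside;
    every update preserves nonnegativity, the list-mode Poisson
    log-likelihood is nondecreasing, and after each update the image
    satisfies ``sum_j lambda_j s_j = number of used events``.  No subsets
    and no post-filtering.
    """
    events = data.events
    if len(events) == 0:
        raise ValueError("cannot reconstruct an empty event set")
    grid = config.grid
    scanner = data.scanner
    sens = (
        config.sensitivity
        if config.sensitivity is not None
        else sensitivity_image(
            scanner,
            grid,
            attenuation_image=config.attenuation_image,
            min_sector_difference=data.header.get("min_sector_difference"),
        )
    )
    sens_flat = np.ascontiguousarray(sens, dtype=float).ravel()
    support = sens_flat > 0

    centers = crystal_centers(scanner)
    n_cr = scanner.n_crystals_per_ring
    flat_a = events["ring_a"].astype(np.int64) * n_cr + events["crystal_a"]
    flat_b = events["ring_b"].astype(np.int64) * n_cr + events["crystal_b"]
    pa = centers[flat_a]
    pb = centers[flat_b]
    dt = np.ascontiguousarray(events["delta_t_ps"], dtype=float)
    sig_f, sig_s, alpha, tof_on = config.model.event_kernel_params(events)

    lam = np.where(support, 1.0, 0.0)
    ox, oy, oz = grid.origin_mm
    vx, vy, vz = grid.voxel_size_mm

    save_set = set(config.save_iterations)
    if config.save_every:
        save_set.update(range(config.save_every, config.n_iterations + 1, config.save_every))

    ll_hist = np.empty(config.n_iterations)
    cons_hist = np.empty(config.n_iterations)
    snapshots: dict[int, np.ndarray] = {}
    skipped = 0
    for it in range(1, config.n_iterations + 1):
        back, ll_events, skipped = mlem_pass(
            np.ascontiguousarray(pa[:, 0]), np.ascontiguousarray(pa[:, 1]),
            np.ascontiguousarray(pa[:, 2]),
            np.ascontiguousarray(pb[:, 0]), np.ascontiguousarray(pb[:, 1]),
            np.ascontiguousarray(pb[:, 2]),
            dt,
            np.ascontiguousarray(sig_f), np.ascontiguousarray(sig_s),
            np.ascontiguousarray(alpha),
            tof_on, config.tof_binning.bin_width_ps,
            ox, oy, oz, vx, vy, vz, grid.nx, grid.ny, grid.nz,
            lam, TOF_TRUNCATION_NSIGMA,
        )
        ll_hist[it - 1] = ll_events - float(sens_flat @ lam)
        lam = np.where(support, lam * back / np.where(support, sens_flat, 1.0), 0.0)
        n_used = len(events) - skipped
        cons_hist[it - 1] = abs(float(sens_flat @ lam) - n_used) / max(n_used, 1)
        if it in save_set:
            snapshots[it] = lam.reshape(grid.shape).copy()
    return ReconResult(
        image=lam.reshape(grid.shape),
        snapshots=snapshots,
        log_likelihood=ll_hist,
        conservation_residual=cons_hist,
        n_events_used=len(events) - skipped,
        n_events_skipped=skipped,
        sensitivity=sens,
    )


def calibrate(
    image: np.ndarray, reference_region_mask: np.ndarray, reference_kBq_cc: float
) -> tuple[np.ndarray, float]:
    """Scale an image so the mask's mean equals the reference activity.

    Returns ``(calibrated_image, scale_factor)``.
    """
    mask = np.asarray(reference_region_mask, dtype=bool)
    if not mask.any():
        raise ValueError("calibration mask is empty")
    mean = float(np.asarray(image)[mask].mean())
    if mean <= 0:
        raise ValueError("calibration region mean is not positive")
    scale = reference_kBq_cc / mean
    return np.asarray(image) * scale, scale
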