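"""Potential of mean force from umbrella-sampling windows.

Implements the standard self-consistent weighted-histogram (WHAM)
equations for 1-D umbrella sampling with harmonic biases, in thermal
units, plus block-analysis standard errors. Spring constants follow the
MD convention (kJ mol^-1 nm^-2); positions are in Å.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .units import DEFAULT_TEMPERATURE_K, spring_kj_mol_nm2_to_kBT_A2

DEFAULT_SPRING_KJ_MOL_NM2 = 1000.0
DEFAULT_SPACING_A = 0.25


@dataclass
class UmbrellaWindow:
    """Samples of the reaction coordinate under one harmonic restraint.

    Attributes
    ----------
    center_A : restraint center z_c in Å.
    k_spring : harmonic force constant in kJ mol^-1 nm^-2 (0 = unbiased).
    samples_A : 1-D array of z samples in Å.
    temperature_K : simulation temperature for unit conversion.
    meta : free-form metadata (seed, spacing, overlap warnings, ...).
    """

    center_A: float
    k_spring: float
    samples_A: np.ndarray
    temperature_K: float = DEFAULT_TEMPERATURE_K
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples_A = np.asarray(self.samples_A, dtype=float)
        if self.k_spring < 0:
            raise ValueError("spring constant must be >= 0")
        if self.samples_A.size < 1:
            raise ValueError("window needs at least one sample")

    def bias_kBT(self, z: np.ndarray) -> np.ndarray:
        """Bias energy w(z) = 1/2 k (z - z_c)^2 in kBT."""
        k = spring_kj_mol_nm2_to_kBT_A2(self.k_spring, self.temperature_K)
        return 0.5 * k * (np.asarray(z, dtype=float) - self.center_A) ** 2


@dataclass
class PMFProfile:
    """Free-energy profile along z in kBT, gauged so its minimum is 0."""

    z_A: np.ndarray
    f_kBT: np.ndarray
    se_kBT: Optional[np.ndarray] = None
    n_iter: int = 0
    residual: float = np.inf
    converged: bool = False
    window_f_kBT: Optional[np.ndarray] = None

    def barrier_kBT(self) -> float:
        """Highest point of the profile relative to its global minimum."""
        return float(np.nanmax(self.f_kBT))


class WhamConvergenceError(RuntimeError):
    pass


def _window_histograms(windows: Sequence[UmbrellaWindow], bin_width_A: float):
    lo = min(w.samples_A.min() for w in windows)
    hi = max(w.samples_A.max() for w in windows)
    n_bins = max(int(np.ceil((hi - lo) / bin_width_A)), 1)
    edges = lo + bin_width_A * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.stack([np.histogram(w.samples_A, bins=edges)[0] for w in windows])
    return centers, counts


def check_overlap(windows: Sequence[UmbrellaWindow], bin_width_A: float = 0.25):
    """Return z locations of sampling gaps between adjacent window supports."""
    centers, counts = _window_histograms(windows, bin_width_A)
    total = counts.sum(axis=0)
    gaps = centers[(total == 0)]
    return gaps


def wham(
    windows: Sequence[UmbrellaWindow],
    bin_width_A: float = 0.25,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    n_blocks: int = 0,
) -> PMFProfile:
    """Self-consistent WHAM estimate of the unbiased PMF.

    Iterates, in log space for numerical stability,

        f_i  <- -ln sum_z rho(z) exp(-w_i(z))
        rho(z) <- sum_i n_i(z) / sum_i N_i exp(f_i - w_i(z))

    until the largest change in any window free energy f_i falls below
    ``tol`` (kBT). The PMF is -ln rho gauged to min 0. With ``n_blocks``
    >= 2, per-bin standard errors are estimated by block analysis: each
    window's time series is cut into contiguous blocks, WHAM is re-run per
    block, and the SE of the (gauge-aligned) block PMFs is reported.

    Raises :class:`WhamConvergenceError` when window supports do not
    overlap (reporting the gap location); exceeding ``max_iter`` returns an
    unconverged profile with ``converged=False`` rather than failing
    silently.
    """
    if len(windows) == 0:
        raise ValueError("no windows")
    centers, counts = _window_histograms(windows, bin_width_A)
    gaps = centers[(counts.sum(axis=0) == 0)]
    # only gaps between the outermost restraint centers break the ladder;
    # sparse histogram tails beyond them are harmless
    c_lo = min(w.center_A for w in windows)
    c_hi = max(w.center_A for w in windows)
    interior_gaps = gaps[(gaps > c_lo) & (gaps < c_hi)]
    if interior_gaps.size:
        raise WhamConvergenceError(
            f"windows do not overlap: no samples near z = {interior_gaps[0]:.2f} A"
        )

    n_win = len(windows)
    M = counts.sum(axis=0).astype(float)  # samples per bin
    keep = M > 0
    if n_win > 1:
        # report the PMF only over the restraint ladder, as sparse
        # histogram tails beyond the outer centers are pure noise
        keep &= (centers >= c_lo) & (centers <= c_hi)
    centers_k = centers[keep]
    # N_i must count only the samples that landed in kept bins, or the
    # normalization sum_z M_z = sum_i N_i breaks and the estimate is biased
    counts_k = counts[:, keep]
    N = counts_k.sum(axis=1).astype(float)
    if np.any(N == 0):
        raise WhamConvergenceError("a window has no samples on the PMF grid")
    M_k = counts_k.sum(axis=0).astype(float)
    # bias matrix w[i, z] in kBT
    w = np.stack([win.bias_kBT(centers_k) for win in windows])

    f = np.zeros(n_win)
    log_N = np.log(N)
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # log rho(z) = ln M_z - logsumexp_i(ln N_i + f_i - w_iz)
        log_rho = np.log(M_k) - logsumexp(log_N[:, None] + f[:, None] - w, axis=0)
        f_new = -logsumexp(log_rho[None, :] - w, axis=1)
        f_new -= f_new[0]  # gauge
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            break
    converged = residual < tol
    if not converged:
        warnings.warn(
            f"WHAM not converged after {max_iter} iterations (residual {residual:.2e} kBT)",
            RuntimeWarning,
            stacklevel=2,
        )
    log_rho = np.log(M_k) - logsumexp(log_N[:, None] + f[:, None] - w, axis=0)
    pmf = -log_rho
    pmf -= pmf.min()

    se = None
    if n_blocks >= 2:
        block_pmfs = []
        for b in range(n_blocks):
            bw = []
            for win in windows:
                s = win.samples_A
                L = len(s) // n_blocks
                if L < 1:
                    raise ValueError("fewer samples than blocks in a window")
                bw.append(
                    UmbrellaWindow(
                        center_A=win.center_A,
                        k_spring=win.k_spring,
                        samples_A=s[b * L : (b + 1) * L],
                        temperature_K=win.temperature_K,
                    )
                )
            prof_b = wham(bw, bin_width_A=bin_width_A, tol=tol, max_iter=max_iter)
            block_pmfs.append(np.interp(centers_k, prof_b.z_A, prof_b.f_kBT))
        B = np.stack(block_pmfs)
        B -= B.mean(axis=1, keepdims=True)  # align additive gauges
        se = B.std(axis=0, ddof=1) / np.sqrt(n_blocks)

    return PMFProfile(
        z_A=centers_k,
        f_kBT=pmf,
        se_kBT=se,
        n_iter=it,
        residual=residual,
        converged=converged,
        window_f_kBT=f,
    )


def block_error(samples: np.ndarray, n_blocks: int = 5) -> float:
    """Standard error of the mean by block analysis.

    The series is cut into ``n_blocks`` contiguous blocks (truncating any
    remainder) and SE = std(block means, ddof=1) / sqrt(n_blocks) — a crude
    but standard guard against serial correlation.
    """
    samples = np.asarray(samples, dtype=float)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    L = samples.size // n_blocks
    if L < 1:
        raise ValueError(f"fewer samples ({samples.size}) than blocks ({n_blocks})")
    means = samples[: L * n_blocks].reshape(n_blocks, L).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


# ---------------------------------------------------------------------------
# Window I/O: one TSV per window + JSON sidecar
# ---------------------------------------------------------------------------

def write_windows(windows: Sequence[UmbrellaWindow], directory: str | Path, dt_ns: float = 0.01) -> list[Path]:
    """Write each window as ``window_###.tsv`` (time_ns, z_A) + sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, w in enumerate(windows):
        p = directory / f"window_{i:03d}.tsv"
        t = dt_ns * np.arange(len(w.samples_A))
        np.savetxt(
            p,
            np.column_stack([t, w.samples_A]),
            delimiter="\t",
            header="time_ns\tz_A",
            comments="",
            fmt="%.6f",
        )
        side = {
            "center_A": w.center_A,
            "k_spring_kJ_mol_nm2": w.k_spring,
            "temperature_K": w.temperature_K,
            **w.meta,
        }
        p.with_suffix(".tsv.json").write_text(json.dumps(side, indent=1))
        paths.append(p)
    return paths


def read_windows(directory: str | Path) -> list[UmbrellaWindow]:
    directory = Path(directory)
    windows = []
    for p in sorted(directory.glob("window_*.tsv")):
        data = np.loadtxt(p, delimiter="\t", skiprows=1, ndmin=2)
        side = json.loads(p.with_suffix(".tsv.json").read_text())
        windows.append(
            UmbrellaWindow(
                center_A=float(side["center_A"]),
                k_spring=float(side["k_spring_kJ_mol_nm2"]),
                samples_A=data[:, 1],
                temperature_K=float(side.get("temperature_K", DEFAULT_TEMPERATURE_K)),
                meta={k: v for k, v in side.items()
                      if k not in ("center_A", "k_spring_kJ_mol_nm2", "temperature_K")},
            )
        )
    if not windows:
        raise FileNotFoundError(f"no window_*.tsv files in {directory}")
    return windows


def write_pmf(profile: PMFProfile, path: str | Path) -> None:
    se = profile.se_kBT if profile.se_kBT is not None else np.zeros_like(profile.f_kBT)
    np.savetxt(
        path,
        np.column_stack([profile.z_A, profile.f_kBT, se]),
        delimiter="\t",
        header="z_A\tF_kBT\tSE_kBT",
        comments="",
        fmt="%.6f",
    )
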