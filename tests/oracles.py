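"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorized implementation paths: the event
oracle walks continuous (unwrapped) coordinates frame by frame against all
periodic images of the crossing planes, and the WHAM oracle solves the
maximum-likelihood equations by direct convex minimization instead of
fixed-point iteration.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


def oracle_events_continuous(z_cont, times, z_sf, z_gate, box_length_z):
    """Frame-by-frame event scan on continuous coordinates.

    A wrapped crossing of plane p corresponds to a continuous crossing of
    any image p + n*L. Returns (direction, t_enter, t_exit) tuples.
    """
    L = box_length_z
    events = []
    armed_in = armed_out = False
    t_in = t_out = 0.0

    def images_crossed(a, b, p):
        # integer n with a side != b side of p + n*L, ordered along motion
        lo, hi = (a, b) if a < b else (b, a)
        n_min = math.ceil((lo - p) / L)
        n_max = math.floor((hi - p) / L)
        out = []
        for n in range(n_min, n_max + 1):
            q = p + n * L
            # downward: a > q >= b ; upward: a <= q < b
            if a > q >= b or a <= q < b:
                out.append(q)
        return out

    for i in range(len(z_cont) - 1):
        a, b = z_cont[i], z_cont[i + 1]
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        sf_x = images_crossed(a, b, z_sf)
        gate_x = images_crossed(a, b, z_gate)
        if b < a:  # downward: SF images before gate images along motion
            both = sorted(sf_x + gate_x, reverse=True)
            for q in both:
                t = float(times[i + 1])
                if q in sf_x:
                    armed_in = True
                    # double crossing in one step: enter at the prior frame
                    t_in = float(times[i]) if gate_x else t
                else:
                    if armed_in:
                        events.append(("inward", t_in, t))
                        armed_in = False
                    armed_out = False
        elif b > a:  # upward: gate images before SF images
            both = sorted(sf_x + gate_x)
            for q in both:
                t = float(times[i + 1])
                if q in gate_x:
                    armed_out = True
                    t_out = float(times[i]) if sf_x else t
                else:
                    if armed_out:
                        events.append(("outward", t_out, t))
                        armed_out = False
                    armed_in = False
    return events


def oracle_wham_mle(windows, bin_width_A=0.25):
    """WHAM free energies by direct minimization of the convex likelihood.

    Minimizes Phi(f) = sum_z M_z ln sum_i N_i exp(f_i - w_i(z))
                       - sum_i N_i f_i   (gauge f_0 = 0)
    and returns (bin centers, PMF in kBT gauged to min 0).
    """
    c_lo = min(w.center_A for w in windows)
    c_hi = max(w.center_A for w in windows)
    lo = min(w.samples_A.min() for w in windows)
    hi = max(w.samples_A.max() for w in windows)
    n_bins = int(np.ceil((hi - lo) / bin_width_A))
    edges = lo + bin_width_A * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.stack([np.histogram(w.samples_A, bins=edges)[0] for w in windows])
    M = counts.sum(axis=0).astype(float)
    keep = (M > 0) & (centers >= c_lo) & (centers <= c_hi)
    w_mat = np.stack([w.bias_kBT(centers[keep]) for w in windows])
    # count only samples on the kept grid so sum_z M_z = sum_i N_i holds
    N = counts[:, keep].sum(axis=1).astype(float)
    M_k = counts[:, keep].sum(axis=0).astype(float)
    log_N = np.log(N)

    def phi_and_grad(f_free):
        f = np.concatenate([[0.0], f_free])
        inner = log_N[:, None] + f[:, None] - w_mat  # (n_win, n_bins)
        lse = logsumexp(inner, axis=0)
        phi = float(np.sum(M_k * lse) - np.sum(N * f))
        resp = np.exp(inner - lse[None, :])  # softmax over windows
        grad = resp @ M_k - N
        return phi, grad[1:]

    n_win = len(windows)
    res = minimize(
        phi_and_grad,
        np.zeros(n_win - 1),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10},
    )
    f = np.concatenate([[0.0], res.x])
    lse = logsumexp(log_N[:, None] + f[:, None] - w_mat, axis=0)
    log_rho = np.log(M_k) - lse
    pmf = -log_rho
    pmf -= pmf.min()
    return centers[keep], pmf
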