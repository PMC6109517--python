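"""Beta-mixture quantile dilation (BMIQ-style) normalization.

Infinium 450K arrays mix two probe chemistries whose beta-value
distributions differ systematically: type-II probes are compressed toward
0.5 relative to type-I probes. Normalization fits, per sample, a
three-component beta mixture (unmethylated U, hemimethylated H,
methylated M states) separately to the type-I and type-II probes, then
maps type-II values onto the type-I reference:

* U-class probes (max-posterior assignment) via the quantile map
  q = F_inv[U, I](F[U, II](beta)) of the fitted beta CDFs;
* M-class probes analogously with the upper-tail convention,
  q = 1 - F_inv-tail, so the fully methylated end anchors at 1;
* H-class probes by linear dilation of their observed range onto the
  interval bounded by the transformed U-class upper end and the
  transformed M-class lower end (keeping the gaps observed between the
  classes on the input scale), preserving ranks.

Type-I probes are untouched. The mixture is fitted by EM with an exact
weighted maximum-likelihood M-step, so the log-likelihood is
non-decreasing across iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .containers import BetaMatrix

logger = logging.getLogger(__name__)

EPS = 1e-6


class MixtureError(ValueError):
    pass


@dataclass
class BetaMixtureFit:
    """A fitted 3-component beta mixture, components ordered U < H < M."""

    weights: np.ndarray  # (3,)
    a: np.ndarray  # (3,) shape-1 per component
    b: np.ndarray  # (3,) shape-2 per component
    responsibilities: np.ndarray  # (n, 3)
    loglik: float
    loglik_trace: np.ndarray
    n_iter: int

    @property
    def means(self) -> np.ndarray:
        return self.a / (self.a + self.b)

    def classify(self, values: np.ndarray) -> np.ndarray:
        """Max-posterior component index (0=U, 1=H, 2=M) for new values."""
        x = np.clip(values, EPS, 1 - EPS)
        logp = np.log(self.weights)[None, :] + stats.beta.logpdf(
            x[:, None], self.a[None, :], self.b[None, :]
        )
        return np.argmax(logp, axis=1)


def _moment_shapes(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted method-of-moments beta shapes, clipped to a sane range."""
    wsum = w.sum()
    m = float((w * x).sum() / wsum)
    v = float((w * (x - m) ** 2).sum() / wsum)
    m = min(max(m, 1e-3), 1 - 1e-3)
    v = max(v, 1e-6)
    common = max(m * (1 - m) / v - 1, 1e-2)
    return float(np.clip(m * common, 1e-2, 1e4)), float(np.clip((1 - m) * common, 1e-2, 1e4))


def _mle_shapes(slx: float, sl1x: float, r: float, a0: float, b0: float) -> tuple[float, float]:
    """Maximize the weighted beta log-likelihood given sufficient stats.

    slx = sum(w * log x), sl1x = sum(w * log(1-x)), r = sum(w).
    Optimized over log-shapes with analytic gradients.
    """

    def negll(theta):
        a, b = np.exp(theta)
        val = r * special.betaln(a, b) - (a - 1) * slx - (b - 1) * sl1x
        dig = special.digamma
        da = (r * (dig(a) - dig(a + b)) - slx) * a
        db = (r * (dig(b) - dig(a + b)) - sl1x) * b
        return val, np.array([da, db])

    res = optimize.minimize(
        negll, np.log([a0, b0]), jac=True, method="L-BFGS-B",
        bounds=[(np.log(1e-3), np.log(1e5))] * 2,
    )
    a, b = np.exp(res.x)
    return float(a), float(b)


def fit_beta_mixture(
    values: np.ndarray, tol: float = 1e-5, max_iter: int = 500
) -> BetaMixtureFit:
    """EM fit of a 3-component beta mixture to values in (0, 1).

    Initialization: 1-d k-means seeded at the 1/6, 3/6, 5/6 quantiles,
    then method-of-moments shapes per cluster. Components are relabeled
    by ascending mean so index 0/1/2 is always U/H/M.

    Raises :class:`MixtureError` on degenerate input (fewer than 30
    values, or all values identical).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 30:
        raise MixtureError("need at least 30 values to fit a 3-component mixture")
    x = np.clip(x, EPS, 1 - EPS)
    if np.ptp(x) < 1e-12:
        raise MixtureError("mixture unidentifiable: all values identical")

    # quantile-seeded 1-d k-means
    centers = np.quantile(x, [1 / 6, 3 / 6, 5 / 6])
    for _ in range(50):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array([x[assign == k].mean() if (assign == k).any() else centers[k]
                        for k in range(3)])
        if np.allclose(new, centers, atol=1e-10):
            break
        centers = new
    a = np.empty(3)
    b = np.empty(3)
    w = np.empty(3)
    for k in range(3):
        mask = assign == k
        if mask.sum() < 2:
            # fall back to a diffuse component at the seed center
            c = min(max(centers[k], 1e-3), 1 - 1e-3)
            a[k], b[k], w[k] = 2 * c, 2 * (1 - c), 1.0 / x.size
        else:
            a[k], b[k] = _moment_shapes(x[mask], np.ones(mask.sum()))
            w[k] = mask.mean()
    w = np.maximum(w, 1e-6)
    w /= w.sum()

    lx, l1x = np.log(x), np.log1p(-x)
    trace = []
    loglik = -np.inf
    resp = np.full((x.size, 3), 1 / 3)
    for it in range(1, max_iter + 1):
        logp = np.log(w)[None, :] + stats.beta.logpdf(x[:, None], a[None, :], b[None, :])
        norm = special.logsumexp(logp, axis=1)
        new_loglik = float(norm.sum())
        resp = np.exp(logp - norm[:, None])
        trace.append(new_loglik)
        if it > 1 and abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            break
        loglik = new_loglik
        # M-step: exact weighted MLE per component
        r = resp.sum(axis=0)
        w = r / r.sum()
        for k in range(3):
            if r[k] < 1e-8:
                continue
            slx = float(resp[:, k] @ lx)
            sl1x = float(resp[:, k] @ l1x)
            a[k], b[k] = _mle_shapes(slx, sl1x, float(r[k]), a[k], b[k])

    order = np.argsort(a / (a + b))
    return BetaMixtureFit(
        weights=w[order], a=a[order], b=b[order],
        responsibilities=resp[:, order], loglik=loglik,
        loglik_trace=np.asarray(trace), n_iter=len(trace),
    )


def _normalize_sample(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Map one sample's type-II values onto its type-I reference."""
    fit1 = fit_beta_mixture(v1)
    fit2 = fit_beta_mixture(v2)
    x = np.clip(v2, EPS, 1 - EPS)
    cls = fit2.classify(x)
    out = x.copy()

    u_mask, h_mask, m_mask = cls == 0, cls == 1, cls == 2
    if u_mask.any():
        p = stats.beta.cdf(x[u_mask], fit2.a[0], fit2.b[0])
        out[u_mask] = stats.beta.ppf(p, fit1.a[0], fit1.b[0])
    if m_mask.any():
        # upper-tail convention: anchor the methylated end at 1
        p = stats.beta.sf(x[m_mask], fit2.a[2], fit2.b[2])
        out[m_mask] = stats.beta.isf(p, fit1.a[2], fit1.b[2])
    if h_mask.any():
        lo_src = x[h_mask].min()
        hi_src = x[h_mask].max()
        # target boundaries sit beyond the transformed U-upper / M-lower
        # ends by the same gaps observed on the input scale, so the
        # dilation only tracks how much the flanking classes moved
        if u_mask.any():
            lo_dst = out[u_mask].max() + (lo_src - x[u_mask].max())
        else:
            lo_dst = lo_src
        if m_mask.any():
            hi_dst = out[m_mask].min() - (x[m_mask].min() - hi_src)
        else:
            hi_dst = hi_src
        if hi_dst <= lo_dst:  # guard against crossing boundaries
            lo_dst, hi_dst = lo_src, hi_src
        if hi_src > lo_src:
            out[h_mask] = lo_dst + (x[h_mask] - lo_src) * (hi_dst - lo_dst) / (hi_src - lo_src)
        else:
            out[h_mask] = 0.5 * (lo_dst + hi_dst)
    return np.clip(out, 0.0, 1.0)


def bmiq_normalize(beta: BetaMatrix, ann: pd.DataFrame) -> tuple[BetaMatrix, list[str]]:
    """Normalize every sample's type-II probes to its type-I reference.

    Returns the normalized matrix and the list of samples left
    unnormalized because a mixture fit failed (also logged as warnings).
    """
    sub = ann.loc[beta.probe_ids]
    is1 = (sub["design_type"] == "I").to_numpy()
    is2 = ~is1
    if not is1.any() or not is2.any():
        raise MixtureError("both design types must be present")
    values = beta.values.to_numpy(dtype=float).copy()
    failed: list[str] = []
    for j, sample in enumerate(beta.sample_ids):
        col = values[:, j]
        try:
            col[is2] = _normalize_sample(col[is1], col[is2])
        except MixtureError as exc:
            failed.append(str(sample))
            logger.warning("sample %s left unnormalized: %s", sample, exc)
    out = beta.copy()
    out.values = pd.DataFrame(values, index=beta.probe_ids, columns=beta.sample_ids)
    return out, failed
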