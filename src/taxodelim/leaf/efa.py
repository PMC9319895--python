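"""Elliptic Fourier analysis of closed outlines.

The chain of contour increments is decomposed into harmonic coefficients
(a_n, b_n, c_n, d_n) following Kuhl & Giardina's formulation; the usual
normalization removes size, rotation and starting point by standardizing
the first harmonic ellipse (after it, a1 = 1 and b1 = c1 = 0, so the
non-trivial shape information lives in d1 and the higher harmonics).
The constant (DC) terms A0/C0 carry location only and are excluded from
downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class EfaDescriptors:
    """Harmonic coefficients of one outline, rows = (a, b, c, d)."""

    coefficients: np.ndarray  # (harmonics, 4)
    normalized: bool
    a0: float = 0.0
    c0: float = 0.0

    @property
    def harmonics(self) -> int:
        return self.coefficients.shape[0]

    def flatten(self, drop_trivial: bool = True) -> np.ndarray:
        """Coefficient vector for multivariate analysis.

        When normalized and ``drop_trivial``, the fixed entries a1, b1, c1
        (1, 0, 0 by construction) are omitted.
        """
        flat = self.coefficients.ravel()
        if self.normalized and drop_trivial:
            return flat[3:]
        return flat


def _close(contour: np.ndarray) -> np.ndarray:
    contour = np.asarray(contour, dtype=float)
    if np.allclose(contour[0], contour[-1]):
        return contour
    return np.vstack([contour, contour[:1]])


def resample_contour(contour: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed contour to n points equally spaced by arc length."""
    ring = _close(contour)
    seg = np.linalg.norm(np.diff(ring, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    s = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(s, cum, ring[:, 0])
    y = np.interp(s, cum, ring[:, 1])
    return np.column_stack([x, y])


def efa(
    contour: np.ndarray, harmonics: int = 15, normalize: bool = True
) -> EfaDescriptors:
    """Elliptic Fourier descriptors of a closed polygon outline."""
    contour = np.asarray(contour, dtype=float)
    if len(contour) < 3:
        raise ValueError("degenerate contour")
    if len(contour) < 3 * harmonics:
        contour = resample_contour(contour, max(3 * harmonics, 64))
    ring = _close(contour)
    d = np.diff(ring, axis=0)
    dt = np.linalg.norm(d, axis=1)
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    if T == 0:
        raise ValueError("degenerate contour")
    phi = 2.0 * np.pi * t / T
    n = np.arange(1, harmonics + 1)[:, None]
    const = T / (2.0 * np.pi**2 * np.arange(1, harmonics + 1) ** 2)
    dcos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    dsin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    a = const * ((d[:, 0] / dt) * dcos).sum(axis=1)
    b = const * ((d[:, 0] / dt) * dsin).sum(axis=1)
    c = const * ((d[:, 1] / dt) * dcos).sum(axis=1)
    dd = const * ((d[:, 1] / dt) * dsin).sum(axis=1)
    coeffs = np.column_stack([a, b, c, dd])

    # DC terms (location)
    xi = np.cumsum(d[:, 0]) - d[:, 0] / dt * t[1:]
    delta = np.cumsum(d[:, 1]) - d[:, 1] / dt * t[1:]
    a0 = (
        (d[:, 0] / (2 * dt) * (t[1:] ** 2 - t[:-1] ** 2) + xi * dt).sum() / T
    )
    c0 = (
        (d[:, 1] / (2 * dt) * (t[1:] ** 2 - t[:-1] ** 2) + delta * dt).sum() / T
    )

    if normalize:
        coeffs = _normalize(coeffs)
    return EfaDescriptors(coeffs, normalized=normalize, a0=float(a0), c0=float(c0))


def _apply_normalization(coeffs: np.ndarray, theta: float) -> np.ndarray:
    """Start-shift by theta, rotate onto the first semi-axis, rescale."""
    out = coeffs.copy()
    n = np.arange(1, len(coeffs) + 1)
    cos_nt, sin_nt = np.cos(n * theta), np.sin(n * theta)
    for i in range(len(coeffs)):
        a, b, c, d = out[i]
        m = np.array([[a, b], [c, d]]) @ np.array(
            [[cos_nt[i], -sin_nt[i]], [sin_nt[i], cos_nt[i]]]
        )
        out[i] = m.ravel()
    a1s, _, c1s, _ = out[0]
    psi = np.arctan2(c1s, a1s)
    rot = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    for i in range(len(coeffs)):
        m = rot @ np.array([[out[i, 0], out[i, 1]], [out[i, 2], out[i, 3]]])
        out[i] = m.ravel()
    scale = out[0, 0]
    if scale == 0:
        raise ValueError("degenerate first harmonic")
    return out / scale


def _normalize(coeffs: np.ndarray) -> np.ndarray:
    """Standardize size, rotation and starting point via the 1st harmonic.

    The phase formula fixes the starting point only up to a quarter
    period (major vs minor axis) and a half period (the two ends of the
    major axis); the four candidates are resolved deterministically by
    discarding minor-axis starts (|d1| > 1 after rescaling) and taking
    the lexicographically largest coefficient vector of the remainder,
    which is a function of the outline geometry alone -- hence invariant
    to input rotation and starting vertex.
    """
    a1, b1, c1, d1 = coeffs[0]
    theta = 0.5 * np.arctan2(
        2.0 * (a1 * b1 + c1 * d1), a1**2 - b1**2 + c1**2 - d1**2
    )
    candidates = []
    for k in range(4):
        cand = _apply_normalization(coeffs, theta + k * np.pi / 2.0)
        if abs(cand[0, 3]) <= 1.0 + 1e-9:
            candidates.append(np.round(cand, 12))
    if not candidates:
        candidates = [np.round(_apply_normalization(coeffs, theta), 12)]
    return max(candidates, key=lambda c: tuple(c.ravel()))


def reconstruct(
    desc: EfaDescriptors, n_points: int = 256, harmonics: int | None = None
) -> np.ndarray:
    """Outline reconstructed from the first ``harmonics`` coefficients."""
    h = harmonics or desc.harmonics
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    x = np.full_like(t, desc.a0 if not desc.normalized else 0.0)
    y = np.full_like(t, desc.c0 if not desc.normalized else 0.0)
    for i in range(h):
        a, b, c, d = desc.coefficients[i]
        x = x + a * np.cos((i + 1) * t) + b * np.sin((i + 1) * t)
        y = y + c * np.cos((i + 1) * t) + d * np.sin((i + 1) * t)
    return np.column_stack([x, y])


def efa_pca(descriptors: list[EfaDescriptors]):
    """PCA (centered, covariance) of the non-constant descriptors.

    Returns ``(scores, variance_explained, components)``; the first two
    score columns feed the shape permutation test.
    """
    from sklearn.decomposition import PCA

    if len(descriptors) < 2:
        raise ValueError("need at least two outlines")
    X = np.vstack([d.flatten() for d in descriptors])
    n_comp = min(X.shape[0] - 1, X.shape[1])
    if np.allclose(X.var(axis=0), 0.0):
        return (
            np.zeros((X.shape[0], max(n_comp, 2))),
            np.zeros(max(n_comp, 2)),
            np.zeros((max(n_comp, 2), X.shape[1])),
        )
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_, pca.components_
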