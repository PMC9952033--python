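"""Two-iteration non-local Bayes patch-group denoiser.

Each square patch of the noisy image is modeled as a draw from a Gaussian
whose mean and covariance are estimated over its group of most similar
patches inside a local search window.  The patch is then shrunk toward the
group mean by a Wiener-type filter built from the group covariance and the
noise variance.  The procedure runs twice: the second pass re-groups and
re-estimates statistics on the first pass's output (the "oracle" image),
while the innovation term is still taken from the original noisy patches.

Parameter selection follows fixed sigma-driven rules: patch sides e1/e2 come
from piecewise breakpoints on sigma, group sizes are N = 3 e^2, search
half-widths are ceil(N / 2), and the grouping threshold is tau0 = 16 e2^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .imageprep import as_gray_image

__all__ = [
    "NLBParams",
    "Patch",
    "PatchGroup",
    "DenoiseResult",
    "select_params",
    "extract_patches",
    "patches_at",
    "patch_distance",
    "find_similar",
    "group_stats",
    "bayes_shrink_step1",
    "bayes_shrink_step2",
    "aggregate_patches",
    "denoise",
    "mmse_patch_estimate",
]

# Relative eigenvalue floor applied to group covariances before solving.
_EIG_FLOOR_REL = 1e-8


@dataclass(frozen=True)
class NLBParams:
    """Sigma-derived denoiser parameters (patch sides, group sizes, window, threshold)."""

    e1: int
    e2: int
    N1: int
    N2: int
    lambda1: int
    lambda2: int
    tau0: float
    sigma: float

    def __post_init__(self) -> None:
        if self.e1 not in (3, 5, 7) or self.e2 not in (3, 5, 7):
            raise ValueError("patch sides must be in {3, 5, 7}")
        if self.N1 != 3 * self.e1**2 or self.N2 != 3 * self.e2**2:
            raise ValueError("group sizes must satisfy N = 3 e^2")
        if self.lambda1 != math.ceil(self.N1 / 2) or self.lambda2 != math.ceil(self.N2 / 2):
            raise ValueError("search half-widths must satisfy lambda = ceil(N / 2)")
        if self.tau0 != 16 * self.e2**2:
            raise ValueError("threshold must satisfy tau0 = 16 e2^2")

    def for_iteration(self, iteration: int) -> tuple[int, int, int]:
        """Return (patch side, group size, search half-width) for iteration 1 or 2."""
        if iteration == 1:
            return self.e1, self.N1, self.lambda1
        if iteration == 2:
            return self.e2, self.N2, self.lambda2
        raise ValueError(f"iteration must be 1 or 2, got {iteration}")


@dataclass(frozen=True)
class Patch:
    """A flattened e x e window anchored at its top-left corner (row, col)."""

    values: np.ndarray
    anchor: tuple[int, int]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        side = math.isqrt(v.size)
        if side * side != v.size or v.ndim != 1:
            raise ValueError(f"patch length must be a perfect square, got {v.shape}")

    @property
    def side(self) -> int:
        return math.isqrt(self.values.size)


@dataclass
class PatchGroup:
    """A reference patch with its similar patches and their sample statistics."""

    reference: Patch
    members: list[Patch]
    mean: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    cov: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def member_matrix(self) -> np.ndarray:
        """Stack member values as an (n_members, e^2) matrix."""
        return np.stack([m.values for m in self.members])

    def anchors(self) -> list[tuple[int, int]]:
        return [m.anchor for m in self.members]


@dataclass(frozen=True)
class DenoiseResult:
    basic: np.ndarray
    final: np.ndarray
    coverage: np.ndarray


def select_params(sigma: float) -> NLBParams:
    """Derive all denoiser parameters from the noise level.

    e1 is 3 for sigma <= 20, 5 for 20 < sigma <= 50, 7 otherwise; e2 is 3 for
    sigma <= 50, 5 for 50 < sigma <= 70, 7 otherwise.  N_k = 3 e_k^2,
    lambda_k = ceil(N_k / 2), tau0 = 16 e2^2.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    e1 = 3 if sigma <= 20 else (5 if sigma <= 50 else 7)
    e2 = 3 if sigma <= 50 else (5 if sigma <= 70 else 7)
    n1, n2 = 3 * e1**2, 3 * e2**2
    return NLBParams(
        e1=e1,
        e2=e2,
        N1=n1,
        N2=n2,
        lambda1=math.ceil(n1 / 2),
        lambda2=math.ceil(n2 / 2),
        tau0=float(16 * e2**2),
        sigma=float(sigma),
    )


def _patch_views(image: np.ndarray, e: int) -> np.ndarray:
    """All e x e patches flattened row-major, shape (H-e+1, W-e+1, e^2)."""
    return sliding_window_view(image, (e, e)).reshape(
        image.shape[0] - e + 1, image.shape[1] - e + 1, e * e
    )


def _stride_grid(n_anchors: int, stride: int) -> np.ndarray:
    """Anchor coordinates 0, stride, 2*stride, ... plus the last valid anchor."""
    grid = list(range(0, n_anchors, stride))
    if grid[-1] != n_anchors - 1:
        grid.append(n_anchors - 1)
    return np.asarray(grid)


def extract_patches(image, e: int, stride: int = 1) -> list[Patch]:
    """Decompose an image into flattened e x e patches on a stride grid.

    Anchors lie on the stride lattice plus the last valid row/column, so every
    pixel is covered by at least one patch.
    """
    img = as_gray_image(image, min_side=e)
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    flat = _patch_views(img, e)
    rows = _stride_grid(flat.shape[0], stride)
    cols = _stride_grid(flat.shape[1], stride)
    return [Patch(flat[r, c].copy(), (int(r), int(c))) for r in rows for c in cols]


def patches_at(image, anchors, e: int) -> list[Patch]:
    """Extract the e x e patches at the given (row, col) anchors."""
    img = as_gray_image(image, min_side=e)
    flat = _patch_views(img, e)
    return [Patch(flat[r, c].copy(), (int(r), int(c))) for r, c in anchors]


def patch_distance(p: Patch, q: Patch) -> float:
    """Mean per-pixel squared difference between two equally sized patches."""
    if p.values.size != q.values.size:
        raise ValueError(f"patch length mismatch: {p.values.size} vs {q.values.size}")
    d = p.values - q.values
    return float(np.mean(d * d))


def _select_member_anchors(
    guide_flat: np.ndarray,
    ref_r: int,
    ref_c: int,
    lam: int,
    n_group: int,
    tau0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Choose group member anchors for one reference patch.

    Candidates are all patch anchors within the search window of half-width
    ``lam`` (clipped to the image).  Those with mean squared distance to the
    reference <= tau0 are retained and the ``n_group`` nearest kept; if fewer
    than ``n_group`` pass, the nearest ``n_group`` candidates are used
    regardless.  Ties are broken by (row, col) order of anchors; the reference
    itself is always a member.
    """
    n_rows, n_cols, _ = guide_flat.shape
    r0, r1 = max(ref_r - lam, 0), min(ref_r + lam, n_rows - 1)
    c0, c1 = max(ref_c - lam, 0), min(ref_c + lam, n_cols - 1)
    width = c1 - c0 + 1
    cand = guide_flat[r0 : r1 + 1, c0 : c1 + 1]
    ref = guide_flat[ref_r, ref_c]
    diff = cand - ref
    d2 = np.mean(diff * diff, axis=-1).ravel()
    # stable sort on row-major flat index == (row, col) lexicographic tie-break
    order = np.argsort(d2, kind="stable")
    n_take = min(n_group, d2.size)
    passing = order[d2[order] <= tau0]
    pool = passing if passing.size >= n_take else order
    sel = pool[:n_take].copy()
    ref_flat = (ref_r - r0) * width + (ref_c - c0)
    if ref_flat not in sel:
        sel[-1] = ref_flat
    return r0 + sel // width, c0 + sel % width


def find_similar(
    reference: Patch,
    image,
    params: NLBParams,
    iteration: int = 1,
    guide=None,
) -> PatchGroup:
    """Group the patches most similar to ``reference`` inside its search window.

    Distances are computed on ``guide`` when given (the second-iteration
    oracle image), otherwise on ``image``; member patch values are taken from
    ``image``.  Group statistics are filled in via :func:`group_stats`.
    """
    e, n_group, lam = params.for_iteration(iteration)
    if reference.side != e:
        raise ValueError(f"reference side {reference.side} != iteration-{iteration} side {e}")
    img = as_gray_image(image, min_side=e)
    guide_img = img if guide is None else as_gray_image(guide, min_side=e)
    if guide_img.shape != img.shape:
        raise ValueError("guide and image shapes differ")
    guide_flat = _patch_views(guide_img, e)
    rows, cols = _select_member_anchors(
        guide_flat, reference.anchor[0], reference.anchor[1], lam, n_group, params.tau0
    )
    members = patches_at(img, zip(rows.tolist(), cols.tolist()), e)
    group = PatchGroup(reference=reference, members=members)
    group.mean, group.cov = group_stats(group)
    return group


def group_stats(group: PatchGroup) -> tuple[np.ndarray, np.ndarray]:
    """Sample mean and covariance (divisor n-1, symmetrized) of group members."""
    mat = group.member_matrix()
    if mat.shape[0] < 2:
        raise ValueError(f"need >= 2 members for statistics, got {mat.shape[0]}")
    mean = mat.mean(axis=0)
    dev = mat - mean
    cov = dev.T @ dev / (mat.shape[0] - 1)
    cov = (cov + cov.T) / 2
    return mean, cov


def _shrinkage_basis(cov: np.ndarray, sigma2: float, variant: str) -> tuple[np.ndarray, np.ndarray] | None:
    """Eigenbasis V and filter gains f of the Wiener-type shrinkage matrix.

    ``printed`` uses f = w / (w + sigma^2); ``classic`` uses
    f = max(w - sigma^2, 0) / w.  Covariance eigenvalues are floored at a
    small multiple of the mean diagonal before filtering.  Returns None when
    the filter cannot be formed finitely (degenerate covariance), in which
    case the caller falls back to the group mean.
    """
    w, v = np.linalg.eigh(cov)
    floor = _EIG_FLOOR_REL * max(np.trace(cov), 0.0) / cov.shape[0]
    w = np.maximum(w, floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        if variant == "printed":
            f = w / (w + sigma2)
        elif variant == "classic":
            f = np.maximum(w - sigma2, 0.0) / w
        else:
            raise ValueError(f"unknown step-1 filter variant: {variant!r}")
    if not np.isfinite(f).all():
        return None
    return v, f


def _apply_shrinkage(
    deviations: np.ndarray, base_mean: np.ndarray, cov: np.ndarray, sigma2: float, variant: str
) -> np.ndarray:
    basis = _shrinkage_basis(cov, sigma2, variant)
    if basis is None:
        return np.broadcast_to(base_mean, deviations.shape).copy()
    v, f = basis
    return base_mean + (deviations @ v) * f @ v.T


def bayes_shrink_step1(group: PatchGroup, sigma: float, variant: str = "printed") -> list[Patch]:
    """First-pass Wiener shrinkage of every group member toward the group mean.

    Each member P becomes P_bar + F (P - P_bar) with F built from the noisy
    group covariance and sigma^2 (variant ``printed``: C [C + sigma^2 I]^-1;
    ``classic``: (C - sigma^2 I)_+ C^-1).
    """
    if group.mean is None or group.cov is None:
        group.mean, group.cov = group_stats(group)
    mat = group.member_matrix()
    est = _apply_shrinkage(mat - group.mean, group.mean, group.cov, sigma**2, variant)
    return [Patch(row, m.anchor) for row, m in zip(est, group.members)]


def bayes_shrink_step2(group_noisy: PatchGroup, group_basic: PatchGroup, sigma: float) -> list[Patch]:
    """Second-pass shrinkage using oracle statistics from the basic estimate.

    Outputs P1_bar + C1 [C1 + sigma^2 I]^-1 (Pn - Pn_bar) per member: mean and
    covariance from the first-pass (basic) patches, innovation from the noisy
    patches.
    """
    if group_noisy.anchors() != group_basic.anchors():
        raise ValueError("noisy and basic groups must share the same member anchors")
    if group_basic.mean is None or group_basic.cov is None:
        group_basic.mean, group_basic.cov = group_stats(group_basic)
    noisy = group_noisy.member_matrix()
    noisy_mean = noisy.mean(axis=0)
    est = _apply_shrinkage(
        noisy - noisy_mean, group_basic.mean, group_basic.cov, sigma**2, "printed"
    )
    return [Patch(row, m.anchor) for row, m in zip(est, group_noisy.members)]


def aggregate_patches(estimates: list[Patch], shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Recombine overlapping patch estimates into an image.

    Every pixel becomes the unweighted mean of all estimates covering it; the
    per-pixel contribution count is returned alongside.
    """
    total = np.zeros(shape)
    count = np.zeros(shape, dtype=np.int64)
    for p in estimates:
        e = p.side
        r, c = p.anchor
        total[r : r + e, c : c + e] += p.values.reshape(e, e)
        count[r : r + e, c : c + e] += 1
    if (count == 0).any():
        raise ValueError("some pixels are covered by no patch estimate")
    return total / count, count


def _denoise_pass(
    noisy: np.ndarray,
    guide: np.ndarray | None,
    e: int,
    n_group: int,
    lam: int,
    tau0: float,
    sigma: float,
    variant: str,
    flat_trick: bool,
    stride: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One grouping/shrinkage/aggregation sweep; ``guide`` enables oracle mode."""
    h, w = noisy.shape
    noisy_flat = _patch_views(noisy, e)
    n_rows, n_cols, d = noisy_flat.shape
    noisy_mat = noisy_flat.reshape(-1, d)
    second = guide is not None
    if second:
        guide_flat = _patch_views(guide, e)
        guide_mat = guide_flat.reshape(-1, d)
    else:
        guide_flat = noisy_flat
    sigma2 = sigma**2

    est_sum = np.zeros((n_rows * n_cols, d))
    est_cnt = np.zeros(n_rows * n_cols, dtype=np.int64)
    stride = min(stride, e)  # reference patches alone must tile every pixel
    for r in _stride_grid(n_rows, stride):
        for c in _stride_grid(n_cols, stride):
            rows, cols = _select_member_anchors(guide_flat, r, c, lam, n_group, tau0)
            idx = rows * n_cols + cols
            noisy_mem = noisy_mat[idx]
            stats_mem = guide_mat[idx] if second else noisy_mem
            if flat_trick and np.std(noisy_mem, ddof=1) <= sigma:
                out = np.broadcast_to(stats_mem.mean(axis=0), noisy_mem.shape)
            else:
                mean_s = stats_mem.mean(axis=0)
                dev_s = stats_mem - mean_s
                cov = dev_s.T @ dev_s / (len(idx) - 1)
                cov = (cov + cov.T) / 2
                noisy_mean = noisy_mem.mean(axis=0)
                out = _apply_shrinkage(noisy_mem - noisy_mean, mean_s, cov, sigma2, variant)
            est_sum[idx] += out
            est_cnt[idx] += 1

    # fold patch-space sums back onto the pixel grid
    img_sum = np.zeros((h, w))
    img_cnt = np.zeros((h, w), dtype=np.int64)
    est_sum3 = est_sum.reshape(n_rows, n_cols, d)
    est_cnt2 = est_cnt.reshape(n_rows, n_cols)
    for k in range(d):
        di, dj = divmod(k, e)
        img_sum[di : di + n_rows, dj : dj + n_cols] += est_sum3[:, :, k]
        img_cnt[di : di + n_rows, dj : dj + n_cols] += est_cnt2
    if (img_cnt == 0).any():
        raise RuntimeError("stride grid left pixels uncovered")  # pragma: no cover
    return img_sum / img_cnt, img_cnt


def denoise(
    image,
    sigma: float,
    *,
    stride: int = 1,
    step1_filter: str = "printed",
    flat_trick: bool = True,
    params: NLBParams | None = None,
) -> DenoiseResult:
    """Run the full two-iteration non-local Bayes denoiser.

    Iteration 1 groups and shrinks e1-patches of the noisy image (the basic
    estimate); iteration 2 re-groups e2-patches with distances measured on the
    basic image, estimates oracle statistics from basic patches, and filters
    the noisy innovation.  ``sigma = 0`` is accepted and reduces to the
    identity.  ``stride`` subsamples reference patches for speed; every pixel
    remains covered.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if params is None:
        # the sigma -> 0+ limit of the parameter rules applies at sigma = 0
        params = select_params(sigma) if sigma > 0 else select_params(1e-12)
    img = as_gray_image(image, min_side=max(params.e1, params.e2))
    basic, cov1 = _denoise_pass(
        img, None, params.e1, params.N1, params.lambda1, params.tau0,
        sigma, step1_filter, flat_trick, stride,
    )
    final, cov2 = _denoise_pass(
        img, basic, params.e2, params.N2, params.lambda2, params.tau0,
        sigma, "printed", flat_trick, stride,
    )
    return DenoiseResult(basic=basic, final=final, coverage=cov1 + cov2)


def mmse_patch_estimate(target: Patch, candidates: list[Patch], sigma: float) -> Patch:
    """Minimum mean-square-error patch estimate over a candidate set.

    Returns the exp(-||target - P_i||^2 / (2 sigma^2))-weighted mean of the
    candidates; weights are computed in log-space with max-subtraction so the
    largest weight is exactly 1.
    """
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    mat = np.stack([c.values for c in candidates])
    if mat.shape[1] != target.values.size:
        raise ValueError("candidate patch length differs from target")
    logw = -np.sum((mat - target.values) ** 2, axis=1) / (2 * sigma**2)
    w = np.exp(logw - logw.max())
    return Patch(w @ mat / w.sum(), target.anchor)
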