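"""Three-class tissue segmentation of T1-weighted volumes.

A T1 brain volume orders tissue intensities CSF < GM < WM.  The
segmenter fits a three-component univariate Gaussian mixture to the
in-mask intensities by expectation-maximisation, started from a
deterministic quantile initialisation (25th/50th/75th percentiles), and
assigns the fitted components to CSF/GM/WM in increasing order of mean.
Posterior responsibilities become the tissue probability maps; labels
are the argmax.  This is a deliberately self-contained stand-in for
atlas-prior unified segmentation: it carries no spatial priors and no
bias-field model, which is adequate for co-registered, bias-free inputs
and for the phantom-scale validation this package targets.  Externally
produced probability maps can be injected instead
(:func:`accept_external_probmaps`).

The per-tissue intensity statistics (MeanGM, S.D.GM, MeanWM, S.D.WM)
computed here drive the junction thresholds downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .volumes import BinaryMask, Volume3D, require_same_grid

logger = logging.getLogger("fcdkit")

# label codes
BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
LABEL_NAMES = {BACKGROUND: "background", CSF: "csf", GM: "gm", WM: "wm"}


class ConvergenceError(RuntimeError):
    """EM failed to converge within the iteration budget."""


@dataclass
class TissueStats:
    """Per-tissue intensity statistics (sample SD, n-1 denominator)."""

    mean_gm: float
    sd_gm: float
    mean_wm: float
    sd_wm: float
    n_gm: int
    n_wm: int

    def __post_init__(self):
        if self.sd_gm < 0 or self.sd_wm < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_gm < 1 or self.n_wm < 1:
            raise ValueError("need at least one voxel per tissue")
        if not self.mean_wm > self.mean_gm:
            warnings.warn(
                f"mean WM ({self.mean_wm:g}) not above mean GM ({self.mean_gm:g}); "
                "input may not be T1-weighted", stacklevel=2)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("mean_gm", "sd_gm", "mean_wm", "sd_wm", "n_gm", "n_wm")}


@dataclass
class TissueSegmentation:
    """GM/WM/CSF labels, probability maps and intensity statistics."""

    labels: Volume3D               # integer codes BACKGROUND/CSF/GM/WM
    prob_csf: Volume3D
    prob_gm: Volume3D
    prob_wm: Volume3D
    stats: TissueStats = None
    mixture: dict = None           # fitted GMM parameters, if EM was run

    def __post_init__(self):
        require_same_grid([self.labels, self.prob_csf, self.prob_gm, self.prob_wm],
                          "segmentation maps")
        total = self.prob_csf.data + self.prob_gm.data + self.prob_wm.data
        if total.max(initial=0.0) > 1.0 + 1e-6:
            raise ValueError("tissue probabilities sum above 1")

    def label_mask(self, code: int) -> BinaryMask:
        return BinaryMask(data=(self.labels.data == code).astype(np.uint8),
                          affine=self.labels.affine)


# ---------------------------------------------------------------------------
# EM fit

def _em_fit_gmm3(x: np.ndarray, max_iter: int = 500, tol: float = 1e-8):
    """Fit a 3-component univariate GMM by EM with quantile initialisation.

    Returns (weights, means, variances, log-likelihood trace).  The
    log-likelihood is asserted non-decreasing at every iteration (a
    basic EM guarantee; a violation beyond rounding noise indicates a
    defect, not a data problem).
    """
    x = np.asarray(x, float).ravel()
    means = np.percentile(x, [25.0, 50.0, 75.0]).astype(float)
    # break exactly coincident initial means deterministically
    span = float(x.max() - x.min())
    for k in (1, 2):
        if means[k] <= means[k - 1]:
            means[k] = means[k - 1] + 1e-6 * max(span, 1.0)
    var0 = max(float(np.var(x)) / 9.0, 1e-12 * max(span, 1.0) ** 2)
    variances = np.full(3, var0)
    weights = np.full(3, 1.0 / 3.0)
    var_floor = 1e-10 * max(span, 1.0) ** 2

    ll_trace = []
    prev_ll = -np.inf
    resp = None
    for it in range(max_iter):
        # E-step in log space
        log_pdf = (-0.5 * (x[None, :] - means[:, None]) ** 2 / variances[:, None]
                   - 0.5 * np.log(2.0 * np.pi * variances[:, None])
                   + np.log(weights[:, None]))
        m = log_pdf.max(axis=0)
        log_norm = m + np.log(np.exp(log_pdf - m).sum(axis=0))
        ll = float(log_norm.mean())
        assert ll >= prev_ll - 1e-9 * max(1.0, abs(prev_ll)), \
            f"EM log-likelihood decreased at iteration {it}"
        ll_trace.append(ll)
        resp = np.exp(log_pdf - log_norm)
        converged = np.isfinite(prev_ll) and (ll - prev_ll) <= tol * max(1.0, abs(prev_ll))
        prev_ll = ll
        if converged:
            break
        # M-step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        weights = nk / nk.sum()
        means = (resp @ x) / nk
        variances = np.maximum((resp * (x[None, :] - means[:, None]) ** 2).sum(axis=1) / nk,
                               var_floor)
    else:
        delta = ll_trace[-1] - ll_trace[-2] if len(ll_trace) > 1 else np.inf
        raise ConvergenceError(
            f"EM did not converge in {max_iter} iterations "
            f"(final log-likelihood delta {delta:.3e})")
    return weights, means, variances, resp, ll_trace


def segment_tissues(vol: Volume3D, brain_mask: BinaryMask, seed: int = 0,
                    max_iter: int = 500, tol: float = 1e-8,
                    prob_threshold: float = 0.5) -> TissueSegmentation:
    """Segment a T1 volume into CSF/GM/WM inside a brain mask.

    The fit is fully deterministic (quantile initialisation; ``seed`` is
    accepted for interface symmetry with stochastic stages but does not
    influence the result).  Components are assigned to CSF, GM, WM in
    increasing order of fitted mean.  Labels are invariant under affine
    intensity rescaling of the input.
    """
    require_same_grid([vol, brain_mask], "volume and brain mask")
    inside = brain_mask.as_bool()
    if not inside.any():
        raise ValueError("empty brain mask")
    x = vol.data[inside]
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct intensity values inside the mask")

    weights, means, variances, resp, ll_trace = _em_fit_gmm3(x, max_iter=max_iter, tol=tol)
    order = np.argsort(means)  # CSF < GM < WM on T1
    resp = resp[order]
    mixture = {
        "weights": weights[order].tolist(),
        "means": means[order].tolist(),
        "sds": np.sqrt(variances[order]).tolist(),
        "n_iter": len(ll_trace),
        "log_likelihood": ll_trace[-1],
    }
    logger.info("GMM segmentation: means=%s, %d EM iterations",
                np.round(mixture["means"], 3).tolist(), mixture["n_iter"])

    shape = vol.shape
    probs = []
    for k in range(3):
        p = np.zeros(shape)
        p[inside] = resp[k]
        probs.append(vol.with_data(p))
    labels = np.zeros(shape, dtype=int)
    labels[inside] = np.argmax(resp, axis=0) + CSF
    labels_vol = vol.with_data(labels)

    seg = TissueSegmentation(labels=labels_vol, prob_csf=probs[0],
                             prob_gm=probs[1], prob_wm=probs[2], mixture=mixture)
    seg.stats = tissue_stats(vol, seg, prob_threshold=prob_threshold)
    return seg


def accept_external_probmaps(prob_gm: Volume3D, prob_wm: Volume3D, prob_csf: Volume3D,
                             t1: Volume3D = None,
                             prob_threshold: float = 0.5) -> TissueSegmentation:
    """Wrap externally produced tissue probability maps.

    Lets data segmented elsewhere (e.g. an atlas-based tool) enter the
    pipeline.  Labels are derived by argmax; intensity statistics are
    computed from ``t1`` when it is provided.
    """
    require_same_grid([prob_gm, prob_wm, prob_csf], "probability maps")
    stack = np.stack([prob_csf.data, prob_gm.data, prob_wm.data])
    if stack.min() < -1e-6 or stack.max() > 1.0 + 1e-6:
        raise ValueError("probabilities must lie in [0, 1]")
    stack = np.clip(stack, 0.0, 1.0)
    any_tissue = stack.sum(axis=0) > 0
    if not any_tissue.any():
        raise ValueError("no tissue assigned: all probability maps are zero")
    labels = np.zeros(prob_gm.shape, dtype=int)
    labels[any_tissue] = np.argmax(stack, axis=0)[any_tissue] + CSF
    seg = TissueSegmentation(labels=prob_gm.with_data(labels),
                             prob_csf=prob_csf.with_data(stack[0]),
                             prob_gm=prob_gm.with_data(stack[1]),
                             prob_wm=prob_wm.with_data(stack[2]))
    if t1 is not None:
        require_same_grid([t1, prob_gm], "T1 and probability maps")
        seg.stats = tissue_stats(t1, seg, prob_threshold=prob_threshold)
    return seg


def tissue_stats(vol: Volume3D, seg: TissueSegmentation,
                 prob_threshold: float = 0.5) -> TissueStats:
    """Mean/SD of GM and WM intensities over confidently assigned voxels.

    Only voxels with tissue probability above ``prob_threshold``
    contribute; the default 0.5 excludes partial-volume voxels that
    would pull MeanGM and MeanWM toward each other and squeeze the
    junction band.  SD is the sample standard deviation (n-1).
    """
    require_same_grid([vol, seg.prob_gm], "volume and segmentation")
    sel_gm = seg.prob_gm.data > prob_threshold
    sel_wm = seg.prob_wm.data > prob_threshold
    if not sel_gm.any():
        raise ValueError(f"no GM voxels with probability > {prob_threshold}")
    if not sel_wm.any():
        raise ValueError(f"no WM voxels with probability > {prob_threshold}")
    x_gm = vol.data[sel_gm]
    x_wm = vol.data[sel_wm]
    return TissueStats(
        mean_gm=float(x_gm.mean()),
        sd_gm=float(x_gm.std(ddof=1)) if x_gm.size > 1 else 0.0,
        mean_wm=float(x_wm.mean()),
        sd_wm=float(x_wm.std(ddof=1)) if x_wm.size > 1 else 0.0,
        n_gm=int(x_gm.size),
        n_wm=int(x_wm.size),
    )
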