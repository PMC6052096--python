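"""Hybrid surface + volume template similarity and ranked subset selection.

The hybrid score for template j against test image i is

    O_total = O_volume + w_surface * O_surface

where O_volume is a masked intensity similarity (Pearson cross-correlation
in [-1, 1], or normalized mutual information in [1, 2]) and O_surface <= 0
is the negative sum of per-vertex, per-feature absolute deviations between
the template's true features and the features estimated on the test image
along the template surface, each normalized by the library-wide population
SD of that feature at that vertex. O_surface is additionally divided by
(V_total * 9) so that its scale is independent of the surface sampling
resolution and comparable to the [-1, 1] volume term.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix, LibraryFeatureStats, estimate_features_on_test
from .imaging import BinaryMask, Volume3D, dilate_label
from .library import Template, TemplateLibrary


@dataclass
class SelectionConfig:
    w_surface: float = 3.1
    n_a: int = 17
    n_b: int = 8
    volume_similarity: str = "cc"  # "cc" (cross-correlation) or "nmi"
    nmi_bins: int = 32
    max_samples_per_radius: int | None = None
    fast_inside: bool = False

    def __post_init__(self) -> None:
        if self.w_surface < 0:
            raise ValueError("w_surface must be >= 0")
        if not (1 <= self.n_b <= self.n_a):
            raise ValueError("need 1 <= n_b <= n_a")
        if self.volume_similarity not in ("cc", "nmi"):
            raise ValueError("volume_similarity must be 'cc' or 'nmi'")


@dataclass
class SelectionResult:
    id: str
    o_volume: float
    o_surface: float
    o_total: float
    rank: int = -1

    def to_dict(self) -> dict:
        return {"id": self.id, "o_volume": self.o_volume,
                "o_surface": self.o_surface, "o_total": self.o_total,
                "rank": self.rank}


def o_surface(
    true_features: FeatureMatrix,
    est_features: FeatureMatrix,
    stats: LibraryFeatureStats,
) -> float:
    """Normalized surface feature similarity; 0 iff features identical."""
    a, b = true_features.values, est_features.values
    if a.shape != b.shape or a.shape != stats.mean.shape:
        raise ValueError("feature/stats shape mismatch")
    dev = np.abs(a - b) / stats.floored_sd
    return float(-dev.sum() / a.size)


def cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        raise ValueError("constant masked intensities: correlation undefined")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def normalized_mutual_information(a: np.ndarray, b: np.ndarray,
                                  bins: int = 32) -> float:
    """NMI = (H(A)+H(B))/H(A,B) from a joint histogram; range [1, 2]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def entropy(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    h_ab = entropy(p.ravel())
    if h_ab < 1e-12:
        return 2.0  # both images constant: identical (degenerate) histograms
    return (entropy(pa) + entropy(pb)) / h_ab


def o_volume(
    template_vol: Volume3D,
    test_vol: Volume3D,
    mask: BinaryMask,
    method: str = "cc",
    bins: int = 32,
) -> float:
    """Masked volume similarity between a template and the test image."""
    m = mask.data
    if m.sum() < 100:
        raise ValueError("mask must contain >= 100 voxels")
    a = template_vol.data[m]
    b = test_vol.data[m]
    if method == "cc":
        return cross_correlation(a, b)
    if method == "nmi":
        return normalized_mutual_information(a, b, bins=bins)
    raise ValueError(f"unknown volume similarity {method!r}")


def o_total(o_vol: float, o_surf: float, w_surface: float) -> float:
    return o_vol + w_surface * o_surf


def score_template(
    template: Template,
    test: Volume3D,
    stats: LibraryFeatureStats,
    cfg: SelectionConfig,
    grad_mag: np.ndarray | None = None,
) -> SelectionResult:
    """Hybrid score for one template against the test image.

    The template surface is used at its native coordinates (all images share
    the common stereotaxic space); the volume term is computed within the
    template label dilated three times.
    """
    mask = dilate_label(template.label, iterations=3)
    ov = o_volume(template.volume, test, mask, method=cfg.volume_similarity,
                  bins=cfg.nmi_bins)
    est = estimate_features_on_test(
        test, template.surface, max_samples_per_radius=cfg.max_samples_per_radius,
        grad_mag=grad_mag, fast_inside=cfg.fast_inside,
    )
    osf = o_surface(template.features, est, stats)
    return SelectionResult(id=template.id, o_volume=ov, o_surface=osf,
                           o_total=o_total(ov, osf, cfg.w_surface))


def select_subset(
    library: TemplateLibrary,
    test: Volume3D,
    n: int,
    cfg: SelectionConfig,
    exclude_id: str | None = None,
) -> list[SelectionResult]:
    """Rank templates by hybrid similarity, descending; ties by ascending id."""
    from .features import grad_magnitude

    candidates = [t for t in library.templates if t.id != exclude_id]
    if not candidates:
        raise ValueError("empty library")
    if not (1 <= n <= len(candidates)):
        raise ValueError(f"need 1 <= n <= {len(candidates)}, got n={n}")
    gm = grad_magnitude(test)
    results = [score_template(t, test, library.stats, cfg, grad_mag=gm)
               for t in candidates]
    results.sort(key=lambda r: (-r.o_total, r.id))
    for rank, r in enumerate(results):
        r.rank = rank
    return results[:n]
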