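"""Template library: (image, label, corresponded surface, features) bundles."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import mesh as mesh_mod
from .features import (
    FeatureMatrix,
    LibraryFeatureStats,
    compute_vertex_features,
    library_feature_stats,
)
from .imaging import BinaryMask, LabelVolume, Volume3D, dilate_label, save_volume
from .mesh import CorrespondedSurface, label_to_surface, surface_to_label

#: default correspondence sampling level (vertices per structure)
DEFAULT_LEVEL = 4


@dataclass
class Template:
    """One template: MRI, manual label, corresponded surface, true features."""

    id: str
    volume: Volume3D
    label: LabelVolume
    surface: CorrespondedSurface
    features: FeatureMatrix
    group: str = "control"  # "control" or "patient"


@dataclass
class TemplateLibrary:
    templates: list[Template]
    stats: LibraryFeatureStats
    registration_mask: BinaryMask  # union of all labels, dilated 5x

    def __post_init__(self) -> None:
        if len(self.templates) < 2:
            raise ValueError("template library needs N >= 2 templates")
        levels = {t.surface.level for t in self.templates}
        if len(levels) != 1:
            raise ValueError("all template surfaces must share one sampling level")

    @property
    def size(self) -> int:
        return len(self.templates)

    @property
    def level(self) -> int:
        return self.templates[0].surface.level

    def get(self, template_id: str) -> Template:
        for t in self.templates:
            if t.id == template_id:
                return t
        raise KeyError(template_id)

    def cropped(self, margin_mm: float = 10.0) -> "TemplateLibrary":
        """Library restricted to the registration-mask bounding box.

        World-mm geometry is preserved through the affines, so results are
        interchangeable with the full-grid library wherever the discarded
        far-field voxels play no role. The result is memoized.
        """
        cached = getattr(self, "_cropped", None)
        if cached is not None:
            return cached
        from .imaging import crop_volume, mask_bbox_slices

        sl = mask_bbox_slices(self.registration_mask, margin_mm)
        templates = [
            Template(id=t.id, volume=crop_volume(t.volume, sl),
                     label=crop_volume(t.label, sl), surface=t.surface,
                     features=t.features, group=t.group)
            for t in self.templates
        ]
        lib = TemplateLibrary.__new__(TemplateLibrary)
        lib.templates = templates
        lib.stats = self.stats
        lib.registration_mask = crop_volume(self.registration_mask, sl)
        lib._crop_slices = sl
        self._cropped = lib
        return lib

    def subset(self, ids: list[str]) -> "TemplateLibrary":
        """Sub-library keeping the full-library feature statistics and mask."""
        keep = [self.get(i) for i in ids]
        lib = TemplateLibrary.__new__(TemplateLibrary)
        lib.templates = keep
        lib.stats = self.stats
        lib.registration_mask = self.registration_mask
        return lib


def surface_from_label(label: LabelVolume, level: int) -> CorrespondedSurface:
    """Radial parameterization of all three structures of a label volume."""
    meshes, params = [], []
    for name in ("HP", "AM", "EC"):
        m, p = label_to_surface(label, name, level)
        meshes.append(m)
        params.append(p)
    return mesh_mod.concat_surface(meshes, params)


def build_template(
    template_id: str,
    volume: Volume3D,
    label: LabelVolume,
    level: int = DEFAULT_LEVEL,
    group: str = "control",
    surface: CorrespondedSurface | None = None,
    max_samples_per_radius: int | None = None,
    check_voxelization: bool = True,
    fast_inside: bool = False,
) -> Template:
    if not volume.same_geometry(label):
        raise ValueError(f"template {template_id}: volume/label geometry mismatch")
    if surface is None:
        surface = surface_from_label(label, level)
    # The boundary for true features is the template's own surface (the same
    # inside/outside definition used when estimating features on a test
    # image), so a test image identical to the template reproduces the true
    # features exactly.
    feats = compute_vertex_features(
        volume, surface, boundary=None,
        max_samples_per_radius=max_samples_per_radius, fast_inside=fast_inside,
    )
    if check_voxelization:
        recon = surface_to_label(surface, label)
        inter = np.sum((recon.data > 0) & (label.data > 0))
        denom = np.sum(recon.data > 0) + np.sum(label.data > 0)
        if denom and 2.0 * inter / denom < 0.9:
            raise ValueError(
                f"template {template_id}: surface voxelization disagrees with label"
            )
    return Template(id=template_id, volume=volume, label=label, surface=surface,
                    features=feats, group=group)


def build_library(
    templates: list[Template],
) -> TemplateLibrary:
    if len(templates) < 2:
        raise ValueError("template library needs N >= 2 templates")
    stats = library_feature_stats([t.features for t in templates])
    union = np.zeros(templates[0].label.data.shape, dtype=bool)
    for t in templates:
        union |= t.label.data > 0
    union_lab = BinaryMask(data=union, affine=templates[0].label.affine)
    reg_mask = dilate_label(union_lab, iterations=5)
    return TemplateLibrary(templates=templates, stats=stats,
                           registration_mask=reg_mask)


def save_library(library: TemplateLibrary, out_dir: str | Path) -> None:
    """Write a library as NIfTI + OBJ bundles + npz stats + manifest."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"level": library.level, "templates": []}
    for t in library.templates:
        save_volume(t.volume, out_dir / f"{t.id}_image.nii.gz")
        save_volume(t.label, out_dir / f"{t.id}_label.nii.gz")
        mesh_mod.save_surface(t.surface, out_dir, prefix=f"{t.id}_surface")
        np.save(out_dir / f"{t.id}_features.npy", t.features.values)
        manifest["templates"].append({"id": t.id, "group": t.group})
    save_volume(library.registration_mask, out_dir / "registration_mask.nii.gz")
    np.savez(out_dir / "stats.npz", mean=library.stats.mean, sd=library.stats.sd)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_library(out_dir: str | Path) -> TemplateLibrary:
    import json

    from .imaging import load_volume

    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    templates = []
    for entry in manifest["templates"]:
        tid = entry["id"]
        vol = load_volume(out_dir / f"{tid}_image.nii.gz")
        lab = load_volume(out_dir / f"{tid}_label.nii.gz")
        surf = mesh_mod.load_surface(out_dir, prefix=f"{tid}_surface")
        values = np.load(out_dir / f"{tid}_features.npy")
        templates.append(
            Template(id=tid, volume=vol, label=lab, surface=surf,
                     features=FeatureMatrix(values=values, provenance="true"),
                     group=entry.get("group", "control"))
        )
    stats_npz = np.load(out_dir / "stats.npz")
    stats = LibraryFeatureStats(mean=stats_npz["mean"], sd=stats_npz["sd"])
    mask = load_volume(out_dir / "registration_mask.nii.gz")
    reg_mask = BinaryMask(data=mask.data > 0, affine=mask.affine)
    return TemplateLibrary(templates=templates, stats=stats,
                           registration_mask=reg_mask)
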