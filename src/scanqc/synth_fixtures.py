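"""Synthetic phantoms, BIDS trees, sidecars and rating panels for testing.

Every input the QC system consumes can be generated here without any real
data: ellipsoidal "head" phantoms with concentric intensity shells standing
in for T1w/FA volumes, 4D stacks with FSL bval/bvec sidecars standing in for
diffusion scans, disjoint-sphere label maps standing in for parcellations,
BIDS raw + derivative trees with controllable per-run completeness, and
multi-rater rating panels with a tunable agreement level.

The phantoms are geometric, not anatomical: the contracts under test
(slicing, overlay blending, triage partitioning, CSV persistence, agreement
statistics) never depend on anatomy.  All generators are pure functions of
their spec + seed, so identical calls produce identical bytes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

from .bids_index import OutputManifest

__all__ = [
    "PhantomSpec",
    "PanelSpec",
    "make_t1_phantom",
    "make_dwi_phantom",
    "make_labelmap",
    "make_bids_tree",
    "simulate_panel",
    "DEFAULT_MANIFESTS",
]

#: expected outputs per demo pipeline; "tensor" mirrors the four diffusion
#: tensor feature maps (FA, MD, AD, RD) a tensor fit must produce, plus the
#: pipeline's own QC document.
DEFAULT_MANIFESTS = {
    "tensor": OutputManifest("tensor", (
        "*_FA.nii.gz", "*_MD.nii.gz", "*_AD.nii.gz", "*_RD.nii.gz")),
    "segmentation": OutputManifest("segmentation", (
        "*_labels.nii.gz", "*_QC.png")),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic head phantom volume."""

    shape: tuple[int, int, int] = (64, 64, 64)
    n_shells: int = 3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 16 for s in shape):
            raise ValueError(f"shape dims must be >= 16, got {shape}")
        if self.n_shells < 1:
            raise ValueError("n_shells must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "shape", shape)


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of a simulated multi-rater rating panel.

    Each item has a latent true category drawn from ``base_probs``; each
    rater independently reports it with probability ``agreement`` and
    otherwise picks uniformly among the other categories.  ``agreement`` at
    its floor 1/k makes ratings independent of the latent category (the
    chance-agreement null); 1 forces unanimity.
    """

    n_items: int = 100
    n_raters: int = 4
    k: int = 3
    base_probs: tuple[float, ...] = ()
    agreement: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        probs = self.base_probs or tuple([1.0 / self.k] * self.k)
        probs = tuple(float(p) for p in probs)
        if len(probs) != self.k:
            raise ValueError("base_probs length must equal k")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")
        if not (1.0 / self.k <= self.agreement <= 1.0):
            raise ValueError(f"agreement must lie in [1/k, 1], got {self.agreement}")
        if self.n_raters < 2 or self.n_items < 1:
            raise ValueError("need n_raters >= 2 and n_items >= 1")
        object.__setattr__(self, "base_probs", probs)


def _ras_affine() -> np.ndarray:
    return np.diag([1.0, 1.0, 1.0, 1.0])  # 1 mm isotropic, RAS


def _shell_radius(spec: PhantomSpec) -> np.ndarray:
    """Normalized ellipsoid radius per voxel (1.0 at the head boundary)."""
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in spec.shape),
                        indexing="ij")
    r2 = np.zeros(spec.shape)
    for g, s in zip(grids, spec.shape):
        c = (s - 1) / 2.0
        semi = 0.42 * s  # ellipsoid semi-axis: head fills most of the FOV
        r2 += ((g - c) / semi) ** 2
    return np.sqrt(r2)


def make_t1_phantom(spec: PhantomSpec) -> nib.Nifti1Image:
    """Ellipsoidal head with ``n_shells`` concentric intensity bands + noise.

    Noise-free phantoms take exactly ``n_shells + 1`` distinct values
    (background 0 plus one intensity per band, brightest at the centre).
    """
    r = _shell_radius(spec)
    vol = np.zeros(spec.shape, dtype=float)
    inside = r < 1.0
    band = np.minimum((r * spec.n_shells).astype(int), spec.n_shells - 1)
    # intensities 1000, 900, 800, ... from centre outwards
    vol[inside] = 1000.0 - 100.0 * band[inside]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return nib.Nifti1Image(vol, _ras_affine())


def make_labelmap(spec: PhantomSpec, n_labels: int) -> nib.Nifti1Image:
    """``n_labels`` disjoint spheres inside the phantom; label 0 background.

    Sphere centres are spread along the x axis inside the head so every label
    occupies a distinct region.
    """
    if n_labels < 1:
        raise ValueError("n_labels must be >= 1")
    shape = spec.shape
    labels = np.zeros(shape, dtype=np.int16)
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    # centers on a line through the volume middle, radius small enough to
    # keep neighbours disjoint
    span = 0.6 * shape[0]
    xs = np.linspace((shape[0] - span) / 2, (shape[0] + span) / 2, n_labels)
    radius = min(span / (2.0 * n_labels) * 0.9, 0.15 * min(shape))
    cy, cz = (shape[1] - 1) / 2.0, (shape[2] - 1) / 2.0
    for lab, cx in enumerate(xs, start=1):
        d2 = (grids[0] - cx) ** 2 + (grids[1] - cy) ** 2 + (grids[2] - cz) ** 2
        labels[d2 <= radius ** 2] = lab
    return nib.Nifti1Image(labels, _ras_affine())


def make_dwi_phantom(spec: PhantomSpec, n_volumes: int,
                     pe_role: str = "primary"
                     ) -> tuple[nib.Nifti1Image, str, str]:
    """4D stack of noisy phantoms plus FSL bval/bvec sidecar text.

    Returns ``(image, bval_text, bvec_text)``.  The first volume is b=0
    (bval 0, zero bvec column); the rest carry b=1000 with unit gradient
    columns.  ``pe_role`` only affects the BIDS ``dir-`` entity chosen by
    callers writing the files, not the voxel data.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    rng = np.random.default_rng(spec.seed)
    base = np.asarray(make_t1_phantom(spec).dataobj)
    vols = [base]
    for _ in range(n_volumes - 1):
        vols.append(base * 0.5 + rng.normal(0, max(spec.noise_sd, 1.0), size=spec.shape))
    data = np.stack(vols, axis=-1)
    img = nib.Nifti1Image(data, _ras_affine())

    bvals = [0.0] + [1000.0] * (n_volumes - 1)
    dirs = rng.normal(size=(3, n_volumes))
    norms = np.linalg.norm(dirs, axis=0)
    dirs = dirs / norms
    dirs[:, 0] = 0.0  # b=0 volume has a zero gradient column
    bval_text = " ".join(f"{b:g}" for b in bvals) + "\n"
    bvec_text = "\n".join(
        " ".join(f"{dirs[r, v]:.6f}" for v in range(n_volumes)) for r in range(3)
    ) + "\n"
    return img, bval_text, bvec_text


def make_bids_tree(
    root: str,
    n_subjects: int,
    spec: PhantomSpec = PhantomSpec(shape=(16, 16, 16)),
    pipelines: Optional[dict[str, Sequence[bool]]] = None,
    manifests: Optional[dict[str, OutputManifest]] = None,
    dwi_volumes: int = 8,
) -> dict:
    """Write a raw + derivatives BIDS tree and return its ground truth.

    ``pipelines`` maps pipeline name to a per-subject completeness flag list;
    complete runs produce every manifest item, incomplete runs omit the first
    one, so failure detection is exactly predictable from the flags.  A JSON
    ground-truth sidecar is written next to the tree.
    """
    manifests = dict(DEFAULT_MANIFESTS, **(manifests or {}))
    pipelines = pipelines if pipelines is not None else {
        "tensor": [True] * n_subjects}
    subjects = [f"sub-{i + 1:02d}" for i in range(n_subjects)]
    raw_root = os.path.join(root, "rawdata")
    deriv_root = os.path.join(root, "derivatives")
    truth: dict = {"subjects": subjects, "incomplete": {}}

    for si, sub in enumerate(subjects):
        sub_spec = PhantomSpec(shape=spec.shape, n_shells=spec.n_shells,
                               noise_sd=spec.noise_sd, seed=spec.seed + si)
        anat = os.path.join(raw_root, sub, "anat")
        os.makedirs(anat, exist_ok=True)
        nib.save(make_t1_phantom(sub_spec), os.path.join(anat, f"{sub}_T1w.nii.gz"))
        dwi_dir = os.path.join(raw_root, sub, "dwi")
        os.makedirs(dwi_dir, exist_ok=True)
        img, bval, bvec = make_dwi_phantom(sub_spec, dwi_volumes)
        stem = os.path.join(dwi_dir, f"{sub}_dwi")
        nib.save(img, stem + ".nii.gz")
        with open(stem + ".bval", "w") as fh:
            fh.write(bval)
        with open(stem + ".bvec", "w") as fh:
            fh.write(bvec)

    for name, flags in pipelines.items():
        if len(flags) != n_subjects:
            raise ValueError(f"completeness flags for {name!r} must match n_subjects")
        manifest = manifests[name]
        truth["incomplete"][name] = [s for s, ok in zip(subjects, flags) if not ok]
        for si, (sub, complete) in enumerate(zip(subjects, flags)):
            run_dir = os.path.join(deriv_root, name, sub)
            os.makedirs(run_dir, exist_ok=True)
            sub_spec = PhantomSpec(shape=spec.shape, n_shells=spec.n_shells,
                                   noise_sd=spec.noise_sd, seed=spec.seed + 1000 + si)
            items = manifest.expected_items if complete else manifest.expected_items[1:]
            for pat in items:
                fname = pat.replace("*", sub)
                path = os.path.join(run_dir, fname)
                if fname.endswith(".nii.gz"):
                    if "labels" in fname:
                        nib.save(make_labelmap(sub_spec, 5), path)
                    else:
                        nib.save(make_t1_phantom(sub_spec), path)
                elif fname.endswith(".png"):
                    from .render import save_png
                    rng = np.random.default_rng(sub_spec.seed)
                    save_png(rng.integers(0, 255, size=(32, 32, 3)).astype(np.uint8), path)
                else:
                    with open(path, "w") as fh:
                        fh.write("synthetic placeholder\n")
    with open(os.path.join(root, "ground_truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth


def simulate_panel(spec: PanelSpec) -> np.ndarray:
    """Simulate a rating-count panel at a controlled agreement level.

    Returns an ``(n_items, k)`` integer count matrix suitable for
    :class:`scanqc.agreement.RatingPanel`.  Per item the latent category is
    drawn from ``base_probs``; each rater matches it with probability
    ``agreement`` and otherwise errs uniformly over the other k-1 categories.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.k
    latent = rng.choice(k, size=spec.n_items, p=spec.base_probs)
    # per-rater category draw, vectorized: match w.p. a, else uniform other
    match = rng.random((spec.n_items, spec.n_raters)) < spec.agreement
    errs = rng.integers(0, k - 1, size=(spec.n_items, spec.n_raters))
    # map error draw in [0, k-2] to a category != latent
    ratings = np.where(match, latent[:, None],
                       errs + (errs >= latent[:, None]))
    counts = np.zeros((spec.n_items, k), dtype=int)
    for j in range(k):
        counts[:, j] = np.sum(ratings == j, axis=1)
    return counts
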