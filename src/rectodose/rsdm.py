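"""Unfolding of the cumulative rectal surface dose into a 2D dose map.

The rectal surface dose map (RSDM) is the tube surface cut along the
left-lateral anchor line and unrolled slice by slice onto a fixed
1 mm x 1 mm pixel grid.  Rows are longitudinal positions (row 0 is the
superior end), columns run along the circumference: each row holds
``round(circumference)`` foreground pixels, horizontally centered, which
gives the characteristic lens-shaped foreground.  Traversal within a row
goes through the anterior half first, then the posterior half, so the
per-row 50%-of-circumference anterior/posterior split is simply the
first/second half of the foreground run.

Background is NaN (with a boolean mask alongside) so that zero-dose
foreground remains distinguishable from background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

from .surface import SurfaceDose

__all__ = ["RSDM", "unfold", "split_anterior_posterior"]


@dataclass
class RSDM:
    """2D rectal surface dose map at 1 mm x 1 mm resolution."""

    dose: np.ndarray              # (H, W) float, NaN outside foreground
    mask: np.ndarray              # (H, W) bool foreground
    region: str = "whole"         # whole | anterior | posterior
    row_circumference: np.ndarray = field(default=None)  # (H,) mm, whole-rectum
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.dose.shape != self.mask.shape:
            raise ValueError("dose and mask shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dose.shape

    def foreground_values(self) -> np.ndarray:
        return self.dose[self.mask]

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.dose[..., None].astype(np.float32), np.eye(4)),
                 str(path))

    def write_row_metadata(self, path) -> None:
        rows = [{"row": int(i), "width": int(self.mask[i].sum()),
                 "circumference_mm": (float(self.row_circumference[i])
                                      if self.row_circumference is not None else None)}
                for i in range(self.shape[0])]
        with open(path, "w") as fh:
            json.dump({"region": self.region, "meta": self.meta, "rows": rows}, fh)


def _periodic_interp(values: np.ndarray, v_query: np.ndarray) -> np.ndarray:
    """Linear interpolation of a periodic signal sampled at v = k/n."""
    n = len(values)
    x = v_query * n
    i0 = np.floor(x).astype(int) % n
    i1 = (i0 + 1) % n
    w = x - np.floor(x)
    return values[i0] * (1 - w) + values[i1] * w


def unfold(surface_dose: SurfaceDose) -> RSDM:
    """Unroll the 3D surface dose onto the 2D map (whole region).

    Rows are placed at ~1 mm longitudinal pitch (linear interpolation
    between rings in u); within each row the dose is sampled at 1 mm
    arc-length steps around the interpolated ring starting at v = 0 (the
    left-lateral anchor), anterior half first.
    """
    lat = surface_dose.lattice
    length = lat.length
    n_rows = max(int(round(length)), 2)
    # row centres, superior at row 0
    u_rows = (np.arange(n_rows) + 0.5)[::-1] / n_rows

    circs = np.interp(u_rows, lat.u, lat.circumferences)
    widths = np.round(circs).astype(int)
    if np.any(circs < 4):
        raise ValueError("degenerate ring: circumference < 4 mm")
    W = int(widths.max())

    dose = np.full((n_rows, W), np.nan)
    mask = np.zeros((n_rows, W), dtype=bool)
    # per-theta dose interpolated in u for all rows at once
    ring_dose = np.empty((n_rows, lat.n_theta))
    for k in range(lat.n_theta):
        ring_dose[:, k] = np.interp(u_rows, lat.u, surface_dose.dose[:, k])
    for i in range(n_rows):
        w = widths[i]
        vq = (np.arange(w) + 0.5) / w
        row = _periodic_interp(ring_dose[i], vq)
        start = (W - w) // 2
        dose[i, start:start + w] = row
        mask[i, start:start + w] = True
    return RSDM(dose=dose, mask=mask, region="whole", row_circumference=circs,
                meta={"cut": "left-lateral anchor", "row0": "superior",
                      "traversal": "anterior-first"})


def split_anterior_posterior(rsdm: RSDM) -> tuple[RSDM, RSDM]:
    """Split the whole map at 50% of each row's circumference.

    The first half of every foreground run (the anterior traversal)
    becomes the anterior sub-map row, the rest the posterior one; an odd
    foreground width gives the extra pixel to the anterior half.  Each
    sub-map is re-centered in its own (smaller) width.
    """
    if rsdm.region != "whole":
        raise ValueError("input map is already split")
    H, _ = rsdm.shape
    widths = rsdm.mask.sum(axis=1)
    ant_w = (widths + 1) // 2
    post_w = widths // 2
    out = []
    for region, sub_w, offset in (("anterior", ant_w, np.zeros(H, int)),
                                  ("posterior", post_w, ant_w)):
        Wr = int(sub_w.max())
        d = np.full((H, Wr), np.nan)
        m = np.zeros((H, Wr), dtype=bool)
        for i in range(H):
            w = int(sub_w[i])
            if w == 0:
                continue
            run = np.flatnonzero(rsdm.mask[i])
            src = run[int(offset[i]): int(offset[i]) + w]
            start = (Wr - w) // 2
            d[i, start:start + w] = rsdm.dose[i, src]
            m[i, start:start + w] = True
        out.append(RSDM(dose=d, mask=m, region=region,
                        row_circumference=rsdm.row_circumference,
                        meta=dict(rsdm.meta, split="50%-circumference, odd->anterior")))
    return out[0], out[1]


def save_preview(rsdm: RSDM, path, cmap: str = "jet") -> None:
    """PNG preview of the dose map (background transparent)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(rsdm.dose, cmap=cmap, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="EQD2 (Gy)")
    ax.set_title(f"RSDM ({rsdm.region})")
    ax.set_xlabel("circumference (mm)")
    ax.set_ylabel("longitudinal (mm)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
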