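"""Seeded lung-ultrasound phantom generator.

Each phantom emulates the artifact geometry of a B-mode lung frame: a bright
horizontal pleural band, A-lines (reverberation copies of the pleura at
integer multiples of the pleural depth, with geometric intensity decay),
B-lines (vertical hyperechoic streaks from just below the pleural line to the
image bottom), Gaussian boundary blur, and multiplicative log-normal speckle.
The paired ground-truth mask contains the A- and B-line footprints only (the
pleural line is anatomy, not an artifact to count, and is excluded).

Real B-lines erase the A-lines they cross, so when both artifact families are
present the generated A-bands span the widest B-free column interval rather
than the full width; this keeps every mask component separable, which the
geometric counting rules require.  B-line columns are drawn without
replacement from a grid with guaranteed gaps of at least three B-line widths.

Everything is a pure function of the spec (including its seed): identical
specs give bit-identical phantoms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import write_gray_png, write_mask_png
from .postprocess import LineReport

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 224
    width: int = 224
    pleural_depth: int = 32
    n_a_lines: int = 3
    n_b_lines: int = 2
    a_thickness: int = 6
    b_thickness: int = 8
    a_decay: float = 0.8
    speckle_sigma: float = 0.35
    blur_sigma: float = 1.5
    background_level: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_a_lines < 0 or self.n_b_lines < 0:
            raise ValueError("line counts must be non-negative")
        if self.a_thickness < 2 or self.b_thickness < 2:
            raise ValueError("line thicknesses must be >= 2 pixels")
        if not 0 < self.a_decay <= 1:
            raise ValueError("a_decay must lie in (0, 1]")
        if self.pleural_depth * (self.n_a_lines + 1) >= self.height:
            raise ValueError(
                f"{self.n_a_lines} reverberations at depth {self.pleural_depth} "
                f"do not fit in a {self.height}-pixel-tall image")


_PLEURA_INTENSITY = 0.95
_A_INTENSITY = 0.90       # intensity of the first reverberation before decay
_B_INTENSITY = 0.85


def _band_rows(center: int, thickness: int, height: int) -> slice:
    top = max(center - thickness // 2, 0)
    return slice(top, min(top + thickness, height))


def _sample_b_columns(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Column centers for B-lines, pairwise gaps >= 3 x b_thickness."""
    if spec.n_b_lines == 0:
        return np.empty(0, dtype=int)
    step = 4 * spec.b_thickness          # center spacing => edge gap of 3 widths
    margin = 3 * spec.b_thickness
    candidates = np.arange(margin, spec.width - margin + 1, step)
    if len(candidates) < spec.n_b_lines:
        raise ValueError(
            f"cannot place {spec.n_b_lines} separated B-lines of width "
            f"{spec.b_thickness} in a {spec.width}-pixel-wide image")
    cols = rng.choice(candidates, size=spec.n_b_lines, replace=False)
    return np.sort(cols)


def _a_span(spec: PhantomSpec, b_cols: np.ndarray) -> tuple[int, int]:
    """Column interval for A-bands: widest gap clear of every B-line."""
    if len(b_cols) == 0:
        return 0, spec.width
    margin = 3 * spec.b_thickness
    half = spec.b_thickness // 2
    edges = [0]
    for c in b_cols:
        edges.extend([int(c) - half - margin, int(c) + (spec.b_thickness - half)
                      + margin])
    edges.append(spec.width)
    gaps = [(edges[i], edges[i + 1]) for i in range(0, len(edges), 2)]
    lo, hi = max(gaps, key=lambda g: g[1] - g[0])
    lo, hi = max(lo, 0), min(hi, spec.width)
    if hi - lo < max(int(1.5 * spec.a_thickness) + 1, 2):
        raise ValueError("no B-free column interval wide enough for an A-line; "
                         "reduce n_b_lines or the image is too narrow")
    return lo, hi


def generate_phantom(spec: PhantomSpec
                     ) -> tuple[np.ndarray, np.ndarray, LineReport]:
    """One phantom: (image in [0,1], binary mask, ground-truth line report)."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    img = np.full((H, W), spec.background_level, dtype=np.float64)
    mask = np.zeros((H, W), dtype=np.uint8)

    b_cols = _sample_b_columns(spec, rng)

    # pleural line (image only, never in the mask)
    pleura = _band_rows(spec.pleural_depth, spec.a_thickness, H)
    img[pleura, :] = _PLEURA_INTENSITY

    # A-lines: reverberations at k * pleural_depth, k = 2 .. n+1
    a_lo, a_hi = _a_span(spec, b_cols) if spec.n_a_lines else (0, W)
    for k in range(2, spec.n_a_lines + 2):
        rows = _band_rows(k * spec.pleural_depth, spec.a_thickness, H)
        level = _A_INTENSITY * spec.a_decay ** (k - 1)
        img[rows, a_lo:a_hi] = np.maximum(img[rows, a_lo:a_hi], level)
        mask[rows, a_lo:a_hi] = 1
        assert (a_hi - a_lo) / spec.a_thickness >= 1.5

    # B-lines: from just below the pleural band to the image bottom
    b_top = pleura.stop
    for c in b_cols:
        half = spec.b_thickness // 2
        cols = slice(max(int(c) - half, 0),
                     min(int(c) - half + spec.b_thickness, W))
        img[b_top:, cols] = np.maximum(img[b_top:, cols], _B_INTENSITY)
        mask[b_top:, cols] = 1
        assert (H - b_top) / spec.b_thickness >= 1.5

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.speckle_sigma > 0:
        noise = rng.lognormal(mean=-spec.speckle_sigma ** 2 / 2,
                              sigma=spec.speckle_sigma, size=(H, W))
        img = img * noise
    img = np.clip(img, 0.0, 1.0)
    report = LineReport(n_a_lines=spec.n_a_lines, n_b_lines=spec.n_b_lines)
    return img, mask, report


def _stratified_counts(n: int, a_max: int, b_max: int,
                       b_max_mixed: int) -> list[tuple[int, int]]:
    """(n_a, n_b) pairs covering every count 0..max for each line type.

    High B-counts leave no room for an A-band, so when A-lines are present
    the B-count is capped at ``b_max_mixed``; the full B range is covered by
    A-free phantoms.
    """
    base = [(a, b if a == 0 else min(b, b_max_mixed))
            for a in range(a_max + 1) for b in range(b_max + 1)]
    return [base[i % len(base)] for i in range(n)]


def generate_dataset(n: int, out_dir: str | Path, seed: int = 0,
                     spec: PhantomSpec | None = None,
                     a_max: int = 5, b_max: int = 5,
                     b_max_mixed: int = 3) -> pd.DataFrame:
    """Write ``n`` phantom image/mask PNG pairs plus a manifest CSV.

    Per-item seeds are ``seed + index``; counts are stratified over the
    requested ranges.  Returns the manifest (also saved as manifest.csv).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    base = spec or PhantomSpec()
    rows = []
    for i, (n_a, n_b) in enumerate(_stratified_counts(n, a_max, b_max,
                                                      b_max_mixed)):
        s = dataclasses.replace(base, n_a_lines=n_a, n_b_lines=n_b,
                                seed=seed + i)
        img, mask, _ = generate_phantom(s)
        name = f"phantom_{i:04d}.png"
        write_gray_png(out / "images" / name, img)
        write_mask_png(out / "masks" / name, mask)
        rows.append({"filename": name, **dataclasses.asdict(s)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
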