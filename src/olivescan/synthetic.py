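"""Synthetic olive ripening benchmark: trajectories and rendered images.

The generator emulates the statistical structure of a seasonal olive
phenotyping trial with three cultivars belonging to different ripening
groups.  Per cultivar it produces samples over a window of days after pit
hardening (DAPH) with:

* oil concentration (%FW) rising along a logistic curve from a common
  early-season baseline (~5.5 %FW) to a cultivar plateau (16-22 %FW);
* total phenols (mg GAE per g DW) following a truncated downward parabola
  peaking early-to-mid season (highest in the high-phenol cultivar);
* mean R, G, B fruit pixel values following quasi-parabolic curves that
  peak around 40 DAPH and decline as the skin darkens, with per-channel
  peak-time offsets and a ripening-group time shift per cultivar.

Additive Gaussian noise is applied independently per trait and channel.
Samples can optionally be rendered as ellipse clusters on a saturated
blue background (with an optional white reference patch), which gives the
imaging stage ground-truth masks and channel means to recover.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryParams",
    "RenderSpec",
    "default_cultivars",
    "generate_trajectory",
    "generate_dataset",
    "render_sample",
]

#: Column order of the sample table.
SAMPLE_COLUMNS = (
    "sample_id", "cultivar", "t", "r_mean", "g_mean", "b_mean", "oil", "phenols",
)


@dataclass(frozen=True)
class TrajectoryParams:
    """Per-cultivar seasonal trajectory parameters.

    Times are days after pit hardening (DAPH); oil in %FW; phenols in
    mg GAE g^-1 DW; channels in 8-bit pixel units.
    """

    cultivar_id: str
    t_range: tuple[float, float] = (28.0, 112.0)
    oil_base: float = 5.5
    oil_max: float = 22.0
    oil_midpoint: float = 75.0
    oil_rate: float = 0.1
    phenol_peak: float = 41.0
    phenol_peak_time: float = 55.0
    phenol_curvature: float = 0.012
    channel_peak: tuple[float, float, float] = (150.0, 130.0, 60.0)
    channel_peak_time: tuple[float, float, float] = (40.0, 45.0, 55.0)
    channel_curvature: tuple[float, float, float] = (0.016, 0.014, 0.006)
    noise_sd_trait: tuple[float, float] = (0.8, 2.0)  # (oil, phenols)
    noise_sd_channel: tuple[float, float, float] = (2.5, 2.5, 2.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.oil_base < self.oil_max:
            raise ValueError("oil_base must be < oil_max")
        if self.phenol_peak <= 0:
            raise ValueError("phenol_peak must be > 0")
        if not self.t_range[0] < self.t_range[1]:
            raise ValueError("t_range must be increasing")

    def replace(self, **kw) -> "TrajectoryParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class RenderSpec:
    """Layout of a rendered sample image (ellipse fruit cluster on blue)."""

    width: int = 160
    height: int = 120
    background_rgb: tuple[int, int, int] = (30, 60, 160)
    n_fruits: int = 6
    fruit_axes_range: tuple[int, int] = (8, 14)
    fruit_jitter_sd: float = 0.0
    white_patch: tuple[tuple[int, int, int, int], tuple[int, int, int]] | None = None
    seed: int = 0


def _logistic_oil(p: TrajectoryParams, t: np.ndarray) -> np.ndarray:
    return p.oil_base + (p.oil_max - p.oil_base) / (
        1.0 + np.exp(-p.oil_rate * (t - p.oil_midpoint))
    )


def _parabola(peak: float, peak_time: float, curvature: float, t: np.ndarray) -> np.ndarray:
    return peak - curvature * (t - peak_time) ** 2


def generate_trajectory(
    params: TrajectoryParams, n_times: int, reps_per_time: int
) -> pd.DataFrame:
    """Generate the sample records of one cultivar.

    Returns a DataFrame with columns :data:`SAMPLE_COLUMNS`, sorted by
    time; identical ``params`` (including seed) give identical output.
    """
    if n_times < 2:
        raise ValueError("n_times must be >= 2")
    if reps_per_time < 1:
        raise ValueError("reps_per_time must be >= 1")

    rng = np.random.default_rng(params.seed)
    times = np.linspace(params.t_range[0], params.t_range[1], n_times)
    t = np.repeat(times, reps_per_time)
    n = t.size

    oil = _logistic_oil(params, t) + rng.normal(0.0, params.noise_sd_trait[0], n)
    phen_clean = _parabola(
        params.phenol_peak, params.phenol_peak_time, params.phenol_curvature, t
    )
    phenols = np.clip(phen_clean, 0.0, None) + rng.normal(0.0, params.noise_sd_trait[1], n)
    channels = {}
    for i, name in enumerate(("r_mean", "g_mean", "b_mean")):
        clean = _parabola(
            params.channel_peak[i], params.channel_peak_time[i], params.channel_curvature[i], t
        )
        noisy = np.clip(clean, 0.0, 255.0) + rng.normal(0.0, params.noise_sd_channel[i], n)
        channels[name] = np.clip(noisy, 0.0, 255.0)

    rep = np.tile(np.arange(reps_per_time), n_times)
    ids = [
        f"{params.cultivar_id}_t{ti:03d}_r{ri}"
        for ti, ri in zip(np.repeat(np.arange(n_times), reps_per_time), rep)
    ]
    return pd.DataFrame(
        {
            "sample_id": ids,
            "cultivar": params.cultivar_id,
            "t": t,
            "r_mean": channels["r_mean"],
            "g_mean": channels["g_mean"],
            "b_mean": channels["b_mean"],
            "oil": np.clip(oil, 0.0, None),
            "phenols": np.clip(phenols, 0.0, None),
        }
    )


def default_cultivars(master_seed: int = 0) -> list[TrajectoryParams]:
    """Three study-like cultivars spanning early/middle/late ripening.

    The early ripener (Leccino-like) has its channel decline shifted 10
    days earlier and the late ripener (Coratina-like) 10 days later than
    the mid group; the late ripener is also the high-phenol cultivar.
    """
    ss = np.random.SeedSequence(master_seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]

    def shifted(base: TrajectoryParams, days: float) -> TrajectoryParams:
        return base.replace(
            channel_peak_time=tuple(t + days for t in base.channel_peak_time),
        )

    coratina = TrajectoryParams(
        cultivar_id="Coratina",
        oil_max=22.0,
        phenol_peak=41.0,
        channel_peak=(150.0, 130.0, 60.0),
        seed=seeds[0],
    )
    frantoio = TrajectoryParams(
        cultivar_id="Frantoio",
        oil_max=20.0,
        phenol_peak=32.0,
        channel_peak=(155.0, 135.0, 62.0),
        seed=seeds[1],
    )
    leccino = TrajectoryParams(
        cultivar_id="Leccino",
        oil_max=18.0,
        phenol_peak=28.0,
        channel_peak=(138.0, 118.0, 56.0),
        seed=seeds[2],
    )
    return [shifted(coratina, +10.0), frantoio, shifted(leccino, -10.0)]


def generate_dataset(
    param_sets: Sequence[TrajectoryParams],
    n_times: int = 15,
    reps_per_time: int = 3,
    render: RenderSpec | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenate the trajectories of several cultivars.

    With ``render`` given, each sample is also rendered to PNG (image and
    mask) under ``out_dir`` and a manifest mapping sample_id to file paths
    is returned alongside the sample table.
    """
    if not param_sets:
        raise ValueError("at least one cultivar is required")
    ids = [p.cultivar_id for p in param_sets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate cultivar_id in {ids}")

    frames = [generate_trajectory(p, n_times, reps_per_time) for p in param_sets]
    table = pd.concat(frames, ignore_index=True)

    if render is None:
        return table

    from PIL import Image

    if out_dir is None:
        raise ValueError("out_dir is required when rendering")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for i, row in table.iterrows():
        spec_i = dataclasses.replace(render, seed=render.seed + int(i))
        img, mask = render_sample(
            (row.r_mean, row.g_mean, row.b_mean), spec_i
        )
        img_path = out / f"{row.sample_id}.png"
        mask_path = out / f"{row.sample_id}_mask.png"
        Image.fromarray(img).save(img_path)
        Image.fromarray((mask * 255).astype(np.uint8)).save(mask_path)
        manifest_rows.append(
            {"sample_id": row.sample_id, "image": str(img_path), "mask": str(mask_path)}
        )
    return table, pd.DataFrame(manifest_rows)


def render_sample(
    base_rgb: tuple[float, float, float], spec: RenderSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Render one sample as an ellipse cluster on a uniform background.

    Fruits are ellipses filled with ``round(base_rgb)`` plus a per-fruit
    constant jitter drawn from N(0, fruit_jitter_sd); the returned boolean
    mask marks exactly the fruit pixels.  Ellipses lie fully inside the
    frame, do not overlap each other (bounding-box test) and never
    intersect the optional white patch; a frame too small for the
    requested count raises a placement error.
    """
    from skimage.draw import ellipse as draw_ellipse

    rng = np.random.default_rng(spec.seed)
    img = np.empty((spec.height, spec.width, 3), dtype=np.uint8)
    img[:] = np.asarray(spec.background_rgb, dtype=np.uint8)
    mask = np.zeros((spec.height, spec.width), dtype=bool)

    patch_box = None
    if spec.white_patch is not None:
        (x, y, w, h), rgb = spec.white_patch
        img[y : y + h, x : x + w] = np.asarray(rgb, dtype=np.uint8)
        patch_box = (x, y, w, h)

    a_lo, a_hi = spec.fruit_axes_range
    if 2 * a_hi >= min(spec.width, spec.height):
        raise RuntimeError("fruit axes exceed the frame")
    placed = 0
    attempts = 0
    boxes: list[tuple[int, int, int, int]] = []  # x, y, w, h bounding boxes
    if patch_box is not None:
        boxes.append(patch_box)
    max_attempts = 200 * max(spec.n_fruits, 1)
    while placed < spec.n_fruits:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_fruits} fruits in a "
                f"{spec.width}x{spec.height} frame"
            )
        attempts += 1
        ax = int(rng.integers(a_lo, a_hi + 1))
        ay = int(rng.integers(a_lo, a_hi + 1))
        cx = int(rng.integers(ax, spec.width - ax))
        cy = int(rng.integers(ay, spec.height - ay))
        box = (cx - ax, cy - ay, 2 * ax + 1, 2 * ay + 1)
        if any(_boxes_overlap(box, other) for other in boxes):
            continue
        boxes.append(box)
        rr, cc = draw_ellipse(cy, cx, ay, ax, shape=mask.shape)
        jitter = rng.normal(0.0, spec.fruit_jitter_sd, 3) if spec.fruit_jitter_sd > 0 else np.zeros(3)
        color = np.clip(np.floor(np.asarray(base_rgb, dtype=float) + jitter + 0.5), 0, 255)
        img[rr, cc] = color.astype(np.uint8)
        mask[rr, cc] = True
        placed += 1
    return img, mask


def _boxes_overlap(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    return ax < bx + bw and bx < ax + aw and ay < by + bh and by < ay + ah
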