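"""Synthetic fruit cohorts and rendered fruit-plus-chart images with ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, for a study whose raw per-fruit measurements are the input:

* moisture content drawn uniformly within each ripeness class band
  (ripe 24-30%, under-ripe 30-53%, unripe 53-80.1%);
* a linear relation between moisture and load voltage at a calibration load
  (default 1 kΩ): V_L(mV) = c0 + c1·moisture.  The fruit's internal
  resistance is obtained by inverting the voltage divider at that load,
  r_i = r_cal·(v_i/V_L − 1), with lognormal fruit-to-fruit scatter; this is
  a modelling assumption — no parametric r_i(moisture) law is established —
  chosen so the generated data reproduce the approximately linear
  moisture-voltage scatter and the ripe/unripe voltage separation that
  collapses at high load resistance;
* three replicate voltage readings per (fruit, load), with additive
  measurement noise, which the analysis averages;
* a color feature R_ave/G_ave decreasing affinely in moisture (riper fruit
  are redder), with independent Gaussian noise — its noise is independent of
  the battery noise, so the two modalities carry complementary signal;
* photographs: a bright background, an elliptical fruit whose pixel colors
  realise the sample's true R/G ratio (and always fail the bright-background
  rule), a 16-chip chart, and an affine illumination perturbation whose
  ground-truth matrix is recorded.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .battery import BatteryCircuit, FruitSample, load_voltage
from .color import ChartLayout, ChipRegion, ColorTransform
from .moisture import RipenessLabel, label_ripeness

__all__ = [
    "CohortSpec",
    "SampleTruth",
    "ImageTruth",
    "Cohort",
    "InvalidSpecError",
    "generate_cohort",
    "default_chart_layout",
    "random_illumination",
    "render_fruit_image",
    "write_fixtures",
]


class InvalidSpecError(ValueError):
    """Cohort parameters produce physically impossible voltages."""


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the 52-fruit study design: 21 ripe, 15 under-ripe and 16
    unripe fruit; EMF 0.9 V; calibration load 1 kΩ; load sweep from 10 Ω to
    1 MΩ in decades; three replicate readings per load.  The voltage line
    ``vl_intercept + vl_slope · moisture`` (mV at the calibration load) is
    chosen so that the ripe/unripe voltage-difference statistic sits near the
    reported ~76% band at low loads and the calibration slope is ~0.53 %/mV.
    """

    n_ripe: int = 21
    n_under: int = 15
    n_unripe: int = 16
    moisture_ranges: dict = field(
        default_factory=lambda: {
            RipenessLabel.RIPE: (24.0, 30.0),
            RipenessLabel.UNDER_RIPE: (30.0, 53.0),
            RipenessLabel.UNRIPE: (53.0, 80.1),
        }
    )
    v_i_mean: float = 0.9  # volts
    v_i_jitter: float = 0.0  # relative sd of EMF across fruit
    r_cal: float = 1000.0  # ohms, calibration load
    vl_intercept: float = -25.0  # mV at moisture 0 (c0)
    vl_slope: float = 1.9  # mV per % moisture (c1)
    noise_sigma: float = 0.1  # lognormal sigma of r_i scatter
    measurement_noise_mv: float = 1.0  # additive per-replicate sd
    n_replicates: int = 3
    r_l_values: tuple[float, ...] = (10.0, 100.0, 1e3, 1e4, 1e5, 1e6)
    rg_high: float = 1.8  # R/G at the driest fruit (24% moisture)
    rg_low: float = 0.9  # R/G at the wettest fruit (80.1% moisture)
    rg_sigma: float = 0.08  # Gaussian sd of the color feature
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ripe < 0 or self.n_under < 0 or self.n_unripe < 0:
            raise InvalidSpecError("class counts must be non-negative")
        if self.n_ripe + self.n_under + self.n_unripe == 0:
            raise InvalidSpecError("at least one class count must be positive")
        if self.noise_sigma < 0 or self.rg_sigma < 0 or self.measurement_noise_mv < 0:
            raise InvalidSpecError("noise parameters must be non-negative")
        for lo, hi in self.moisture_ranges.values():
            if not (0.0 <= lo <= hi <= 100.0):
                raise InvalidSpecError("moisture ranges must lie within [0, 100]")

    def true_slope(self) -> float:
        """Structural calibration slope of moisture on voltage, %/mV (= 1/c1)."""
        return 1.0 / self.vl_slope

    def rg_of_moisture(self, moisture: np.ndarray | float) -> np.ndarray | float:
        """Noise-free R/G ratio at a given moisture content."""
        lo = self.moisture_ranges[RipenessLabel.RIPE][0]
        hi = self.moisture_ranges[RipenessLabel.UNRIPE][1]
        return self.rg_high + (np.asarray(moisture) - lo) / (hi - lo) * (
            self.rg_low - self.rg_high
        )


@dataclass(frozen=True)
class SampleTruth:
    """Noise-free ground truth for one generated fruit.

    ``true_vl`` holds the exact divider voltage (V) at each swept load for
    the fruit's actual circuit, i.e. before replicate measurement noise.
    """

    sample_id: str
    moisture: float
    circuit: BatteryCircuit
    true_vl: dict[float, float]
    true_r_over_g: float


@dataclass(frozen=True)
class ImageTruth:
    """Ground truth for one rendered photograph."""

    illumination: np.ndarray  # 3x4 affine applied to the frame
    fruit_mask: np.ndarray  # (H, W) bool
    true_r_over_g: float
    contaminated: bool  # illumination pushed fruit pixels into background rule


@dataclass
class Cohort:
    """A generated cohort: samples, ground truth, and raw replicate readings."""

    spec: CohortSpec
    samples: list[FruitSample]
    truth: list[SampleTruth]
    readings: pd.DataFrame  # sample_id, class_label, r_l_ohm, v_l_mV, replicate

    def moisture_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "moisture_pct": [s.moisture for s in self.samples],
            }
        )

    def feature_frame(self, r_l: float | None = None) -> pd.DataFrame:
        """Per-fruit classification features at the calibration load (mV)."""
        r_l = self.spec.r_cal if r_l is None else r_l
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "v_l_mV": [s.voltages[r_l] * 1000.0 for s in self.samples],
                "r_over_g": [s.r_over_g for s in self.samples],
                "label": [s.label.value for s in self.samples],
            }
        )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw one cohort of fruit according to ``spec``.

    Raises
    ------
    InvalidSpecError
        If the voltage line leaves (0, v_i) somewhere in the moisture ranges.
    """
    rng = np.random.default_rng(spec.seed)
    moistures: list[float] = []
    labels: list[RipenessLabel] = []
    for lab, count in (
        (RipenessLabel.RIPE, spec.n_ripe),
        (RipenessLabel.UNDER_RIPE, spec.n_under),
        (RipenessLabel.UNRIPE, spec.n_unripe),
    ):
        lo, hi = spec.moisture_ranges[lab]
        # band boundaries (30, 53) belong to the lower class: open the low end
        # of the draw where the endpoint would label into the class below
        if count > 0 and label_ripeness(lo) is not lab:
            lo = float(np.nextafter(lo, hi))
        moistures.extend(rng.uniform(lo, hi, count))
        labels.extend([lab] * count)

    samples: list[FruitSample] = []
    truth: list[SampleTruth] = []
    rows: list[dict] = []
    for i, (m, lab) in enumerate(zip(moistures, labels)):
        sid = f"S{i + 1:03d}"
        v_i = spec.v_i_mean
        if spec.v_i_jitter > 0:
            v_i *= float(np.exp(rng.normal(0.0, spec.v_i_jitter)))
        target_mv = spec.vl_intercept + spec.vl_slope * m
        if not 0.0 < target_mv < v_i * 1000.0:
            raise InvalidSpecError(
                f"voltage line gives V_L={target_mv:.1f} mV at moisture {m:.1f}% "
                f"(must lie in (0, {v_i * 1000:.0f}) mV)"
            )
        r_i = spec.r_cal * (v_i / (target_mv / 1000.0) - 1.0)
        if spec.noise_sigma > 0:
            r_i *= float(np.exp(rng.normal(0.0, spec.noise_sigma)))
        circuit = BatteryCircuit(v_i=v_i, r_i=r_i)
        true_vl = {r_l: load_voltage(circuit, r_l) for r_l in spec.r_l_values}

        voltages: dict[float, float] = {}
        for r_l in spec.r_l_values:
            reps_mv = true_vl[r_l] * 1000.0 + rng.normal(
                0.0, spec.measurement_noise_mv, spec.n_replicates
            )
            voltages[r_l] = float(np.mean(reps_mv)) / 1000.0
            for rep, v_mv in enumerate(reps_mv, start=1):
                rows.append(
                    {
                        "sample_id": sid,
                        "class_label": lab.value,
                        "r_l_ohm": r_l,
                        "v_l_mV": float(v_mv),
                        "replicate": rep,
                    }
                )

        rg_true = float(spec.rg_of_moisture(m))
        rg = rg_true + float(rng.normal(0.0, spec.rg_sigma)) if spec.rg_sigma > 0 else rg_true
        samples.append(
            FruitSample(
                sample_id=sid, label=lab, moisture=float(m), voltages=voltages, r_over_g=rg
            )
        )
        truth.append(
            SampleTruth(
                sample_id=sid,
                moisture=float(m),
                circuit=circuit,
                true_vl=true_vl,
                true_r_over_g=rg_true,
            )
        )
    readings = pd.DataFrame(rows, columns=["sample_id", "class_label", "r_l_ohm", "v_l_mV", "replicate"])
    return Cohort(spec=spec, samples=samples, truth=truth, readings=readings)


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

#: Reference colors of the synthetic 16-chip chart.  All channels sit in
#: [100, 195]: bright enough that, once an image is corrected, every chip
#: pixel satisfies the bright-background rule (all channels > 90) and the
#: chart removes itself from the fruit's foreground; capped low enough that
#: realistic illumination gains never clip chip pixels at 255.
_CHART_PALETTE: tuple[tuple[float, float, float], ...] = (
    (190, 100, 100), (100, 180, 100), (100, 100, 190), (185, 175, 105),
    (175, 105, 170), (105, 170, 170), (150, 120, 100), (120, 150, 105),
    (105, 120, 150), (195, 195, 195), (160, 160, 160), (115, 115, 115),
    (185, 140, 115), (140, 115, 100), (100, 140, 115), (115, 100, 140),
)

#: Fruit base green/blue channels; blue stays <= 90 under realistic
#: illumination so fruit pixels always fail the background rule.
_FRUIT_GREEN = 70.0
_FRUIT_BLUE = 40.0
_BACKGROUND_WHITE = 235.0


def default_chart_layout(origin: tuple[float, float] = (16.0, 16.0), cell: float = 24.0,
                         gap: float = 6.0) -> ChartLayout:
    """A synthetic 4x4 16-chip chart with its reference colors.

    Chips are laid out row-major from ``origin`` with ``cell`` px sides and
    ``gap`` px spacing, in image (pixel) coordinates — the identity
    homography is correct for images rendered by this package.
    """
    chips = []
    ref = {}
    for idx, color in enumerate(_CHART_PALETTE):
        row, col = divmod(idx, 4)
        chips.append(
            ChipRegion(
                chip_id=idx,
                x=origin[0] + col * (cell + gap),
                y=origin[1] + row * (cell + gap),
                size=cell,
            )
        )
        ref[idx] = color
    return ChartLayout(chips=tuple(chips), reference_rgb=ref)


def random_illumination(rng: np.random.Generator) -> np.ndarray:
    """A plausible unknown illumination: per-channel gains, small channel
    cross-talk, and offsets, as a 3x4 affine matrix."""
    gains = rng.uniform(0.8, 1.1, 3)
    cross = rng.uniform(-0.04, 0.04, (3, 3))
    np.fill_diagonal(cross, 0.0)
    offsets = rng.uniform(-10.0, 10.0, 3)
    return np.column_stack([np.diag(gains) + cross, offsets])


def render_fruit_image(
    r_over_g: float,
    layout: ChartLayout | None = None,
    illumination: np.ndarray | str | None = "random",
    size: tuple[int, int] = (240, 320),
    seed: int = 0,
    pixel_noise_sigma: float = 2.0,
    fruit_axes: tuple[int, int] = (55, 70),
) -> tuple[np.ndarray, ImageTruth]:
    """Render a fruit-plus-chart photograph whose fruit has a known R/G ratio.

    The scene is a bright background, the 16 chart chips painted at their
    layout positions, and an elliptical fruit on the right of the frame with
    channel values (r_over_g·G, G, B) so the noise-free foreground R/G equals
    ``r_over_g`` exactly.  The illumination matrix (a 3x4 affine in RGB,
    drawn randomly when ``"random"``, identity when None) is applied to the
    whole frame and returned as ground truth.

    Raises
    ------
    ValueError
        If the fruit ellipse is degenerate (zero pixels) or the chart does
        not fit in the frame.
    """
    rng = np.random.default_rng(seed)
    h, w = size
    layout = layout if layout is not None else default_chart_layout()
    img = np.full((h, w, 3), _BACKGROUND_WHITE, dtype=float)

    for chip in layout.chips:
        x0, y0 = int(round(chip.x)), int(round(chip.y))
        x1, y1 = int(round(chip.x + chip.size)), int(round(chip.y + chip.size))
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            raise ValueError(f"chip {chip.chip_id} does not fit in a {w}x{h} frame")
        img[y0:y1, x0:x1] = layout.reference_rgb[chip.chip_id]

    cy, cx = h // 2, int(w * 0.72)
    ay, ax = fruit_axes
    yy, xx = np.mgrid[0:h, 0:w]
    if ay <= 0 or ax <= 0:
        fruit_mask = np.zeros((h, w), dtype=bool)
    else:
        fruit_mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    if not fruit_mask.any():
        raise ValueError("fruit ellipse is degenerate (no pixels)")
    img[fruit_mask] = (r_over_g * _FRUIT_GREEN, _FRUIT_GREEN, _FRUIT_BLUE)

    if pixel_noise_sigma > 0:
        img += rng.normal(0.0, pixel_noise_sigma, img.shape)

    if isinstance(illumination, str):
        if illumination != "random":
            raise ValueError(f"unknown illumination mode {illumination!r}")
        illum = random_illumination(rng)
    elif illumination is None:
        illum = ColorTransform.identity().matrix
    else:
        illum = np.asarray(illumination, dtype=float)
        if illum.shape != (3, 4):
            raise ValueError(f"illumination must be 3x4, got {illum.shape}")

    lit = np.clip(img @ illum[:, :3].T + illum[:, 3], 0.0, 255.0)
    from .color import BACKGROUND_THRESHOLD  # local import avoids cycle at module load

    contaminated = bool(np.all(lit[fruit_mask] > BACKGROUND_THRESHOLD, axis=-1).any())
    return lit, ImageTruth(
        illumination=illum,
        fruit_mask=fruit_mask,
        true_r_over_g=float(r_over_g),
        contaminated=contaminated,
    )


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------


def write_fixtures(outdir: str | Path, spec: CohortSpec | None = None, n_images: int = 6) -> dict:
    """Emit a complete fixture set and return its manifest.

    Writes the cohort's replicate-level battery CSV, moisture CSV and feature
    CSV, the chart layout JSON, ``n_images`` rendered photographs spread
    across ripeness stages, and a JSON manifest recording seeds, file hashes
    and per-image ground truth.
    """
    spec = spec if spec is not None else CohortSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "images").mkdir(exist_ok=True)
    cohort = generate_cohort(spec)
    layout = default_chart_layout()

    paths = {
        "battery_csv": outdir / "battery_readings.csv",
        "moisture_csv": outdir / "moisture.csv",
        "features_csv": outdir / "features.csv",
        "layout_json": outdir / "chart_layout.json",
    }
    cohort.readings.to_csv(paths["battery_csv"], index=False)
    cohort.moisture_frame().to_csv(paths["moisture_csv"], index=False)
    cohort.feature_frame().to_csv(paths["features_csv"], index=False)
    paths["layout_json"].write_text(layout.to_json())

    # spread rendered images across the cohort's ripeness range
    order = np.argsort([s.moisture for s in cohort.samples])
    picks = [cohort.samples[i] for i in order[np.linspace(0, len(order) - 1, n_images).astype(int)]]
    images = []
    for j, sample in enumerate(picks):
        img, truth = render_fruit_image(
            r_over_g=sample.r_over_g, layout=layout, illumination="random",
            seed=spec.seed * 1009 + j,
        )
        png = outdir / "images" / f"{sample.sample_id}.png"
        Image.fromarray(np.clip(np.rint(img), 0, 255).astype(np.uint8)).save(png)
        images.append(
            {
                "sample_id": sample.sample_id,
                "path": str(png.relative_to(outdir)),
                "seed": spec.seed * 1009 + j,
                "true_r_over_g": truth.true_r_over_g,
                "illumination": truth.illumination.tolist(),
                "contaminated": truth.contaminated,
            }
        )

    manifest = {
        "seed": spec.seed,
        "n_samples": len(cohort.samples),
        "class_counts": {
            "ripe": spec.n_ripe, "under_ripe": spec.n_under, "unripe": spec.n_unripe
        },
        "calibration_load_ohm": spec.r_cal,
        "files": {k: str(p.relative_to(outdir)) for k, p in paths.items()},
        "sha256": {
            k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in paths.items()
        },
        "images": images,
        "ground_truth": [
            {
                "sample_id": t.sample_id,
                "moisture": t.moisture,
                "v_i": t.circuit.v_i,
                "r_i": t.circuit.r_i,
                "true_r_over_g": t.true_r_over_g,
            }
            for t in cohort.truth
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
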