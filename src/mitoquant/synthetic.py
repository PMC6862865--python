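"""Synthetic raw-data generators with known ground truth.

Every input family the analysis consumes can be generated here with
hidden true parameters recorded alongside, so that the downstream
modules can be tested by parameter recovery rather than against opaque
fixtures:

- flux plates (per-well OCR/ECAR traces over a basal → oligomycin →
  FCCP → rotenone/antimycin injection sequence),
- single-channel mitochondria images (filled ellipses over noise, with
  the true label map),
- two-channel tandem-reporter images (Gaussian puncta; every green
  punctum is also red, so true autolysosomes = red - green per cell),
- cytometry event samples (two-component log-normal mixtures),
- plate-reader and densitometry tables (signal + normalizer per unit).

All generators are seeded and deterministic: identical truth + seed
yields bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .errors import GenerationError, ScheduleError
from .flux import PHASES, FluxPlate

# --------------------------------------------------------------------------
# Flux plates
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class InjectionSchedule:
    """Measurement-cycle structure of a mito-stress-test run.

    Default: 4 basal cycles then 3 after each injection (13 total); each
    cycle is 30 s mixing followed by 3 min acquisition.
    """

    cycles: tuple = (4, 3, 3, 3)
    mixing_min: float = 0.5
    acquisition_min: float = 3.0

    def __post_init__(self) -> None:
        if len(self.cycles) != len(PHASES):
            raise ScheduleError(
                f"schedule must list cycle counts for phases {PHASES} in order"
            )
        if any(int(c) <= 0 or int(c) != c for c in self.cycles):
            raise ScheduleError("cycle counts must be positive integers")

    @property
    def total_cycles(self) -> int:
        return int(sum(self.cycles))

    @property
    def cycle_min(self) -> float:
        return self.mixing_min + self.acquisition_min

    def phase_labels(self) -> list:
        """Phase label of each cycle, in order."""
        out = []
        for phase, n in zip(PHASES, self.cycles):
            out.extend([phase] * int(n))
        return out

    def times_min(self) -> np.ndarray:
        """Start-of-acquisition time of each cycle (min)."""
        idx = np.arange(self.total_cycles)
        return idx * self.cycle_min + self.mixing_min


@dataclass(frozen=True)
class FluxGroundTruth:
    """Hidden per-well parameters of a synthetic flux well.

    Rates are per-cell-unit; the observed well signal is scaled by
    ``cell_scale`` (a cell-count factor that the normalization signal
    tracks exactly).
    """

    basal_ocr: float
    nonmito_ocr: float
    coupled_fraction: float
    maximal_ocr: float
    ecar: float
    noise_sd: float = 0.0
    cell_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupled_fraction <= 1.0:
            raise ValueError("coupled_fraction must lie in [0, 1]")
        if self.nonmito_ocr > self.basal_ocr:
            raise ValueError("non-mito OCR must not exceed basal OCR")
        if self.maximal_ocr < self.basal_ocr:
            raise ValueError("maximal OCR must be >= basal OCR")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.cell_scale <= 0:
            raise ValueError("cell_scale must be > 0")

    def phase_means(self) -> dict:
        """True phase-level OCR means implied by the parameters."""
        mito = self.basal_ocr - self.nonmito_ocr
        return {
            "basal": self.basal_ocr,
            "oligo": self.nonmito_ocr + (1.0 - self.coupled_fraction) * mito,
            "fccp": self.maximal_ocr,
            "rot_aa": self.nonmito_ocr,
        }


def generate_flux_plate(truths, schedule: InjectionSchedule | None = None,
                        norm_base: float = 1000.0) -> FluxPlate:
    """Generate a flux plate from per-well ground truths.

    Parameters
    ----------
    truths:
        Mapping well-id -> :class:`FluxGroundTruth`, or a sequence (wells
        auto-named ``W01``, ``W02``, ...).
    schedule:
        Injection schedule; default 4+3+3+3 cycles.
    norm_base:
        Normalization signal for a well with ``cell_scale == 1``; the
        per-well signal is exactly ``norm_base * cell_scale``.

    Observed OCR for a cycle in phase *p* is
    ``cell_scale * true_phase_mean(p) + N(0, noise_sd)``; ECAR is
    ``cell_scale * ecar + N(0, noise_sd)``, truncated nowhere.
    """
    schedule = schedule or InjectionSchedule()
    if not isinstance(truths, dict):
        truths = {f"W{i + 1:02d}": t for i, t in enumerate(truths)}
    phases = schedule.phase_labels()
    times = schedule.times_min()
    frames = []
    norm = {}
    for well, truth in truths.items():
        rng = np.random.default_rng(truth.seed)
        means = truth.phase_means()
        ocr = np.array([means[p] for p in phases]) * truth.cell_scale
        ecar = np.full(schedule.total_cycles, truth.ecar * truth.cell_scale)
        if truth.noise_sd > 0:
            ocr = ocr + rng.normal(0.0, truth.noise_sd, ocr.shape)
            ecar = ecar + rng.normal(0.0, truth.noise_sd, ecar.shape)
        frames.append(pd.DataFrame({
            "well": well,
            "cycle": np.arange(1, schedule.total_cycles + 1),
            "phase": phases,
            "time_min": times,
            "OCR": ocr,
            "ECAR": ecar,
        }))
        norm[well] = norm_base * truth.cell_scale
    data = pd.concat(frames, ignore_index=True)
    return FluxPlate(data, normalization=pd.Series(norm, name="signal"))


# --------------------------------------------------------------------------
# Images
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedObject:
    """One planted image object: an ellipse (mitochondrion) or, with
    ``a == b`` interpreted as the spot sd, a Gaussian punctum.

    ``a >= b > 0`` are semi-axes in pixels; ``theta`` is the major-axis
    orientation in radians (counter-clockwise from the column axis).
    True aspect ratio is ``a/b`` and true roundness ``b/a``.
    """

    row: float
    col: float
    a: float
    b: float
    theta: float = 0.0
    intensity: float = 200.0
    cell_id: int = 0
    in_red: bool = True
    in_green: bool = False

    def __post_init__(self) -> None:
        if not self.a >= self.b > 0:
            raise ValueError("semi-axes must satisfy a >= b > 0")

    @property
    def true_aspect_ratio(self) -> float:
        return self.a / self.b

    @property
    def true_roundness(self) -> float:
        return self.b / self.a


@dataclass(frozen=True)
class ImageGroundTruth:
    """Planted objects plus imaging parameters for a synthetic frame."""

    objects: tuple
    shape: tuple = (256, 256)
    background: float = 20.0
    noise_sd: float = 2.0
    seed: int = 0
    cell_grid: tuple = (1, 1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "objects", tuple(self.objects))
        for obj in self.objects:
            r = obj.a
            if not (r <= obj.row <= self.shape[0] - 1 - r
                    and r <= obj.col <= self.shape[1] - 1 - r):
                raise ValueError("planted object does not lie fully inside the frame")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    def cell_id_of(self, row: float, col: float) -> int:
        """Tile index (row-major) of the rectangular cell containing a point."""
        gr, gc = self.cell_grid
        tr = min(int(row / (self.shape[0] / gr)), gr - 1)
        tc = min(int(col / (self.shape[1] / gc)), gc - 1)
        return tr * gc + tc

    def cell_mask(self) -> np.ndarray:
        """Label image of the rectangular cell tiling (labels 1..n_cells)."""
        gr, gc = self.cell_grid
        rows = np.minimum((np.arange(self.shape[0]) / (self.shape[0] / gr)).astype(int), gr - 1)
        cols = np.minimum((np.arange(self.shape[1]) / (self.shape[1] / gc)).astype(int), gc - 1)
        return (rows[:, None] * gc + cols[None, :] + 1).astype(np.int32)


def _noise(shape, background, noise_sd, rng):
    img = np.full(shape, float(background))
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, shape)
    return img


def generate_mito_image(truth: ImageGroundTruth):
    """Render filled ellipses over noisy background.

    Returns ``(image, labels)`` where ``labels`` is the true label map
    (object *i* of ``truth.objects`` has label ``i + 1``; background 0).
    A zero-object truth yields a blank image and an all-zero label map.
    """
    rng = np.random.default_rng(truth.seed)
    img = _noise(truth.shape, truth.background, truth.noise_sd, rng)
    labels = np.zeros(truth.shape, dtype=np.int32)
    for i, obj in enumerate(truth.objects):
        rr, cc = draw_ellipse(obj.row, obj.col, obj.b, obj.a,
                              shape=truth.shape, rotation=obj.theta)
        img[rr, cc] += obj.intensity
        labels[rr, cc] = i + 1
    return img, labels


def _render_spots(img, objects, channel):
    for obj in objects:
        if channel == "red" and not obj.in_red:
            continue
        if channel == "green" and not obj.in_green:
            continue
        sd = obj.a
        half = max(int(np.ceil(4 * sd)), 2)
        r0, c0 = int(round(obj.row)), int(round(obj.col))
        rlo, rhi = max(r0 - half, 0), min(r0 + half + 1, img.shape[0])
        clo, chi = max(c0 - half, 0), min(c0 + half + 1, img.shape[1])
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        img[rlo:rhi, clo:chi] += obj.intensity * np.exp(
            -((rr - obj.row) ** 2 + (cc - obj.col) ** 2) / (2 * sd ** 2)
        )
    return img


def generate_tandem_reporter_image(truth: ImageGroundTruth):
    """Render a two-channel (red, green) tandem-reporter frame.

    Every green punctum must also be red (GFP+ implies RFP+ in the
    tandem construct); a truth violating this is rejected. Returns
    ``(stack, counts)`` where ``stack`` has shape ``(2, H, W)`` in
    channel order red, green, and ``counts`` is a per-cell table of true
    red/green counts, autophagosomes (= green) and autolysosomes
    (= red - green).
    """
    for obj in truth.objects:
        if obj.in_green and not obj.in_red:
            raise ValueError("tandem topology violated: green punctum not in red channel")
    rng = np.random.default_rng(truth.seed)
    red = _render_spots(_noise(truth.shape, truth.background, truth.noise_sd, rng),
                        truth.objects, "red")
    green = _render_spots(_noise(truth.shape, truth.background, truth.noise_sd, rng),
                          truth.objects, "green")
    n_cells = truth.cell_grid[0] * truth.cell_grid[1]
    rows = []
    for cid in range(n_cells):
        objs = [o for o in truth.objects if o.cell_id == cid]
        n_red = sum(o.in_red for o in objs)
        n_green = sum(o.in_green for o in objs)
        rows.append({"cell_id": cid + 1, "red": n_red, "green": n_green,
                     "autophagosomes": n_green, "autolysosomes": n_red - n_green})
    return np.stack([red, green]), pd.DataFrame(rows).set_index("cell_id")


def _place_nonoverlapping(n, shape, rng, margin, min_dist, max_tries_per_object=200):
    """Rejection-sample n centroids with pairwise distance >= min_dist."""
    pts = []
    tries = 0
    budget = n * max_tries_per_object
    while len(pts) < n:
        if tries >= budget:
            raise GenerationError(
                f"could not place {n} non-overlapping objects in frame {shape} "
                f"(min spacing {min_dist:.1f} px) after {budget} tries"
            )
        tries += 1
        r = rng.uniform(margin, shape[0] - 1 - margin)
        c = rng.uniform(margin, shape[1] - 1 - margin)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_dist ** 2 for pr, pc in pts):
            pts.append((r, c))
    return pts


def random_ellipse_truth(n_objects: int, a: float, b: float,
                         shape=(256, 256), theta=None, intensity: float = 200.0,
                         background: float = 20.0, noise_sd: float = 2.0,
                         seed: int = 0) -> ImageGroundTruth:
    """Truth with n identical non-overlapping ellipses at random positions.

    ``theta=None`` draws a uniform random orientation per object.
    """
    rng = np.random.default_rng(seed)
    margin = a + 2
    pts = _place_nonoverlapping(n_objects, shape, rng, margin, min_dist=2 * a + 3)
    objs = []
    for r, c in pts:
        th = rng.uniform(0, np.pi) if theta is None else theta
        objs.append(PlantedObject(row=r, col=c, a=a, b=b, theta=th,
                                  intensity=intensity))
    return ImageGroundTruth(tuple(objs), shape=shape, background=background,
                            noise_sd=noise_sd, seed=seed)


def random_tandem_truth(red_per_cell, green_per_cell, cell_grid=(2, 2),
                        shape=(256, 256), spot_sd: float = 1.5,
                        intensity: float = 150.0, background: float = 10.0,
                        noise_sd: float = 3.0, seed: int = 0) -> ImageGroundTruth:
    """Truth for a tandem-reporter frame with per-cell planted counts.

    ``red_per_cell`` / ``green_per_cell`` are ints (same for all cells)
    or sequences of per-cell counts (row-major tile order); green counts
    must not exceed red counts. Spots within a cell keep >= 8 spot-sd
    centroid spacing and a margin from tile borders so each punctum is
    unambiguously assignable.
    """
    rng = np.random.default_rng(seed)
    gr, gc = cell_grid
    n_cells = gr * gc
    reds = [red_per_cell] * n_cells if np.isscalar(red_per_cell) else list(red_per_cell)
    greens = [green_per_cell] * n_cells if np.isscalar(green_per_cell) else list(green_per_cell)
    if len(reds) != n_cells or len(greens) != n_cells:
        raise ValueError("per-cell counts must match the cell grid size")
    th, tw = shape[0] / gr, shape[1] / gc
    objs = []
    for cid in range(n_cells):
        if greens[cid] > reds[cid]:
            raise ValueError("green count exceeds red count (tandem topology)")
        tr, tc = divmod(cid, gc)
        margin = 4 * spot_sd + 1
        min_dist = 8 * spot_sd
        sub = _place_nonoverlapping(reds[cid], (th - 2, tw - 2), rng,
                                    margin, min_dist)
        for j, (r, c) in enumerate(sub):
            objs.append(PlantedObject(row=tr * th + 1 + r, col=tc * tw + 1 + c,
                                      a=spot_sd, b=spot_sd, intensity=intensity,
                                      cell_id=cid, in_red=True,
                                      in_green=j < greens[cid]))
    return ImageGroundTruth(tuple(objs), shape=shape, background=background,
                            noise_sd=noise_sd, seed=seed, cell_grid=cell_grid)


# --------------------------------------------------------------------------
# Cytometry events, plate-reader and densitometry tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CytometryGroundTruth:
    """Two-component log-normal intensity mixture.

    ``loc``/``scale`` are the underlying normal parameters of each
    component; ``pi_high`` is the probability an event comes from the
    high population.
    """

    pi_high: float
    loc_low: float = np.log(100.0)
    scale_low: float = 0.3
    loc_high: float = np.log(1000.0)
    scale_high: float = 0.3
    n: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_high <= 1.0:
            raise ValueError("pi_high must lie in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def generate_cytometry_events(truth: CytometryGroundTruth) -> np.ndarray:
    """Draw n event intensities from the stated log-normal mixture."""
    rng = np.random.default_rng(truth.seed)
    high = rng.random(truth.n) < truth.pi_high
    vals = np.where(
        high,
        rng.lognormal(truth.loc_high, truth.scale_high, truth.n),
        rng.lognormal(truth.loc_low, truth.scale_low, truth.n),
    )
    return vals


def generate_plate_reader_table(group_ratios: dict, wells_per_group: int = 6,
                                norm_mean: float = 1000.0, cv: float = 0.1,
                                seed: int = 0) -> pd.DataFrame:
    """Plate-reader table with known true signal/normalizer ratios.

    ``group_ratios`` maps group label -> true ratio. Normalizer varies
    log-normally (coefficient of variation ``cv``) emulating well-to-well
    cell-number scatter; signal = ratio * normalizer * (1 + noise).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, ratio in group_ratios.items():
        norm = norm_mean * rng.lognormal(0.0, cv, wells_per_group)
        signal = ratio * norm * (1.0 + rng.normal(0.0, cv, wells_per_group))
        for s, nz in zip(signal, norm):
            rows.append({"group": group, "signal": s, "normalizer": nz})
    return pd.DataFrame(rows)


def generate_densitometry_table(group_ratios: dict, lanes_per_group: int = 4,
                                control_mean: float = 5000.0, cv: float = 0.1,
                                target: str = "alpha-syn", control: str = "Alix",
                                seed: int = 0) -> pd.DataFrame:
    """Densitometry lanes with known true target/loading-control ratios."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, ratio in group_ratios.items():
        ctrl = control_mean * rng.lognormal(0.0, cv, lanes_per_group)
        tgt = ratio * ctrl * (1.0 + rng.normal(0.0, cv, lanes_per_group))
        for t, c in zip(tgt, ctrl):
            rows.append({"group": group, "target": target, "control": control,
                         "signal": t, "normalizer": c})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Ground-truth side-car serialization
# --------------------------------------------------------------------------


def truth_to_json(truth, path) -> None:
    """Write any ground-truth dataclass as a JSON side-car file."""
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2, default=list)
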