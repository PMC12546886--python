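"""Deterministic generators for every test input: the factorial treatment
design, the per-variety seed dataset skeleton, synthetic seed images and
treatment sensor sequences with known ground-truth structure.

Channel map of the generated 50x128 sensor sequence (all scaled to O(1)):

====== ==========================================================
chan    meaning
====== ==========================================================
0       magnetic-field envelope (mT) over the treatment duration
1       normalized seed vibration amplitude at the drive frequency
2       chamber temperature walk, bounded to 22 +/- 2 deg C
3       chamber humidity walk, bounded to 60 +/- 5 %
4       treatment duration / 300 s (constant)
5       duty cycle fraction (constant)
6       pulse width / 10 ms (constant)
7       voltage amplitude / 50 V (constant)
8       drive frequency / 1000 Hz (constant)
9       delivered-dose proxy: field^2 x duration x duty x resonance
10      null channel (wired to have no effect on any target)
11-127  lagged, noisily mixed combinations of channels 0-9
====== ==========================================================
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .phenotype import VarietyProfile, dose_response, effective_dose
from .physics import SeedMechanics, TreatmentProtocol, vibration_amplitude
from .surrogate.train import SurrogateBatch, TARGET_NAMES

DEFAULT_FIELD_LEVELS = (0.5, 1.5, 2.5, 3.5, 5.0)
DEFAULT_FREQUENCY_LEVELS = (50.0, 150.0, 300.0, 500.0, 750.0, 1000.0)
DEFAULT_DURATION_LEVELS = (60.0, 120.0, 180.0, 300.0)

#: fixed values for the three protocol variables not swept by the design
DESIGN_VOLTAGE_V = 27.5
DESIGN_PULSE_MS = 5.0
DESIGN_DUTY_PCT = 50.0

NULL_CHANNEL = 10


@dataclass(frozen=True)
class FactorialDesign:
    field_levels: tuple = DEFAULT_FIELD_LEVELS
    frequency_levels: tuple = DEFAULT_FREQUENCY_LEVELS
    duration_levels: tuple = DEFAULT_DURATION_LEVELS
    seeds_per_cell: int = 50
    replicates: int = 3
    include_control: bool = False

    def __post_init__(self) -> None:
        if not (self.field_levels and self.frequency_levels and self.duration_levels):
            raise ValueError("every factor needs at least one level")


def enumerate_design(design: FactorialDesign) -> list[Optional[TreatmentProtocol]]:
    """Cartesian product of the factor levels, field-major ordering.
    Appends ``None`` (the control arm) when the design flags it."""
    cells: list[Optional[TreatmentProtocol]] = [
        TreatmentProtocol(
            field_strength_mT=b,
            frequency_Hz=f,
            duration_s=t,
            voltage_amplitude_V=DESIGN_VOLTAGE_V,
            pulse_width_ms=DESIGN_PULSE_MS,
            duty_cycle_pct=DESIGN_DUTY_PCT,
        )
        for b, f, t in product(design.field_levels, design.frequency_levels, design.duration_levels)
    ]
    if design.include_control:
        cells.append(None)
    return cells


@dataclass(frozen=True)
class ImageSpec:
    height: int = 64
    width: int = 64
    channels: int = 3
    noise_level: float = 0.02


@dataclass(frozen=True)
class SequenceSpec:
    timesteps: int = 50
    channels: int = 128
    noise_level: float = 0.02


def sample_latent(rng: np.random.Generator, variety_index: int = 0, n_varieties: int = 1) -> dict:
    """Morphology latent in documented ranges.

    The hue latent is variety-coded (each variety occupies one third of the
    hue range) so that variety-level phenotype baselines are recoverable
    from the rendered image, as they would be from real seed-coat colour.
    """
    hue = (variety_index + rng.uniform(0.05, 0.95)) / max(n_varieties, 1)
    return {
        "length": float(rng.uniform(0.40, 0.80)),  # major axis, fraction of frame
        "width": float(rng.uniform(0.20, 0.45)),  # minor axis
        "angle": float(rng.uniform(0.0, np.pi)),
        "hue": float(hue),
        "defect_density": float(rng.uniform(0.0, 5.0)),  # expected defect count
    }


def render_seed_image(spec: ImageSpec, latent: dict, rng: np.random.Generator) -> np.ndarray:
    """Rotated ellipse with hue fill, speckle, Poisson dark defects and
    Gaussian pixel noise; values clipped to [0, 1]."""
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    x = (xx - (w - 1) / 2.0) / (w / 2.0)
    y = (yy - (h - 1) / 2.0) / (h / 2.0)
    ca, sa = np.cos(latent["angle"]), np.sin(latent["angle"])
    xr = ca * x + sa * y
    yr = -sa * x + ca * y
    a = latent["length"] / 2.0 * 2.0  # semi-axis in normalized coords
    b = latent["width"] / 2.0 * 2.0
    mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0

    hue = latent["hue"]
    base = np.array([0.55 + 0.35 * hue, 0.45 + 0.25 * (1.0 - hue), 0.15 + 0.1 * hue])
    img = np.full((h, w, spec.channels), 0.04, dtype=float)
    img[mask] = base

    if spec.noise_level > 0:
        speckle = 1.0 + 0.5 * spec.noise_level * rng.standard_normal((h, w))
        img[mask] *= speckle[mask, None]

    n_defects = rng.poisson(latent["defect_density"]) if latent["defect_density"] > 0 else 0
    ys, xs = np.nonzero(mask)
    for _ in range(n_defects):
        if len(ys) == 0:
            break
        j = rng.integers(len(ys))
        cy, cx = ys[j], xs[j]
        rad = 1 + rng.integers(2)
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
        img[disc & mask] *= 0.25

    if spec.noise_level > 0:
        img += spec.noise_level * rng.standard_normal(img.shape)
    return np.clip(img, 0.0, 1.0)


_MIX_RNG = np.random.default_rng(20240817)
_MIX = _MIX_RNG.standard_normal((118, 10)) * 0.4  # fixed mixing for channels 10+


def render_sequence(
    spec: SequenceSpec,
    protocol: Optional[TreatmentProtocol],
    rng: np.random.Generator,
    mech: Optional[SeedMechanics] = None,
) -> np.ndarray:
    """Sensor sequence for one treatment run; shape (timesteps, channels)."""
    T, C = spec.timesteps, spec.channels
    mech = mech or SeedMechanics(V_seed=2.5e-7, rho_seed=1250.0, f_n=300.0, zeta=0.05)
    seq = np.zeros((T, C), dtype=float)

    if protocol is not None:
        B0 = protocol.field_strength_mT
        rho_f = vibration_amplitude(B0 * 1e-3, protocol.frequency_Hz, mech) / vibration_amplitude(
            B0 * 1e-3, mech.f_n, mech
        )
        seq[:, 0] = B0
        seq[:, 1] = (B0 / 5.0) ** 2 * rho_f
        seq[:, 4] = protocol.duration_s / 300.0
        seq[:, 5] = protocol.duty_fraction
        seq[:, 6] = protocol.pulse_width_ms / 10.0
        seq[:, 7] = protocol.voltage_amplitude_V / 50.0
        seq[:, 8] = protocol.frequency_Hz / 1000.0
        seq[:, 9] = (B0 / 5.0) ** 2 * (protocol.duration_s / 300.0) * protocol.duty_fraction * rho_f

    # bounded environmental random walks (constant at the nominal point
    # when the noise level is zero)
    temp = np.full(T, 22.0)
    hum = np.full(T, 60.0)
    if spec.noise_level > 0:
        temp += np.clip(np.cumsum(rng.normal(0.0, 0.15, T)), -2.0, 2.0)
        hum += np.clip(np.cumsum(rng.normal(0.0, 0.4, T)), -5.0, 5.0)
    seq[:, 2] = np.clip(temp, 20.0, 24.0)
    seq[:, 3] = np.clip(hum, 55.0, 65.0)

    seq[:, NULL_CHANNEL] = 0.5

    base = seq[:, :10]
    mixed = base @ _MIX.T  # (T, 118)
    for i in range(11, C):
        lag = (i - 11) % 5
        seq[:, i] = np.roll(mixed[:, i - 10], lag, axis=0)

    if spec.noise_level > 0:
        seq += spec.noise_level * rng.standard_normal(seq.shape)
        seq[:, 2] = np.clip(seq[:, 2], 20.0, 24.0)
        seq[:, 3] = np.clip(seq[:, 3], 55.0, 65.0)
    return seq


#: sequence-channel groups for permutation attribution
FEATURE_GROUPS = {
    "field_strength": [0],
    "vibration": [1],
    "environment": [2, 3],
    "duration": [4],
    "pulse": [5, 6],
    "voltage": [7],
    "frequency": [8],
    "dose": [9],
    "null": [NULL_CHANNEL],
}


def _record_targets(
    profile: VarietyProfile,
    dose: float,
    latent: dict,
    rng: np.random.Generator,
    noiseless: bool,
) -> np.ndarray:
    dg, dvi = dose_response(dose, profile)
    g = float(np.clip(profile.control_germination_pct + dg, 0.0, 100.0))
    vi = profile.control_vigor_index + dvi
    mean_len = 100.0 * vi / g if g > 0 else 0.0
    seedling = mean_len * latent["length"] / 0.60
    root = profile.root_fraction * seedling * latent["width"] / 0.325
    moisture = 10.0 + 6.0 * latent["hue"]
    response = dg / profile.delta_g_max if profile.delta_g_max else 0.0
    conductivity = 25.0 - 12.0 * response
    t = np.array([g, vi, profile.t50, profile.k, seedling, root, moisture, conductivity])
    if not noiseless:
        t += rng.normal(0.0, [1.0, 1.0, 0.1, 0.02, 2.0, 2.0, 0.3, 0.5])
    return t


def generate_factorial(
    design: FactorialDesign,
    varieties: Sequence[VarietyProfile],
    mech: SeedMechanics,
    rng_seed: int = 0,
    out_dir: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Full factorial experiment: every treatment cell applied to
    ``seeds_per_cell`` seeds x ``replicates`` per variety (phenotype
    records only; image/sequence arrays belong to the dataset mode).
    Each (variety, replicate, cell) triple is one batch.
    """
    from .phenotype import simulate_seed_records

    if not varieties:
        raise ValueError("need at least one variety")
    cells = enumerate_design(design)
    rng = np.random.default_rng(rng_seed)
    frames = []
    for profile in varieties:
        for ci, cell in enumerate(cells):
            recs = simulate_seed_records(
                profile, cell, design.seeds_per_cell, design.replicates, rng, mech
            )
            cell_name = "control" if cell is None else f"c{ci:03d}"
            recs.insert(1, "cell", cell_name)
            recs.insert(
                2,
                "batch_id",
                [
                    f"{profile.name}-{cell_name}-r{r}"
                    for r in recs["replicate"]
                ],
            )
            for fld in (
                "field_strength_mT",
                "frequency_Hz",
                "duration_s",
                "voltage_amplitude_V",
                "pulse_width_ms",
                "duty_cycle_pct",
            ):
                recs[fld] = 0.0 if cell is None else getattr(cell, fld)
            frames.append(recs)
    records = pd.concat(frames, ignore_index=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "records.csv", index=False, float_format="%.8g")
        (out / "manifest.json").write_text(
            json.dumps(
                {
                    "mode": "factorial",
                    "n_records": len(records),
                    "n_cells": len(cells),
                    "rng_seed": rng_seed,
                },
                indent=2,
            )
        )
    return records


def generate_dataset(
    varieties: Sequence[VarietyProfile],
    mech: SeedMechanics,
    n_per_variety: int = 2000,
    rng_seed: int = 0,
    seeds_per_batch: int = 50,
    design: Optional[FactorialDesign] = None,
    noise: str = "full",
    image_spec: Optional[ImageSpec] = None,
    sequence_spec: Optional[SequenceSpec] = None,
    out_dir: Optional[str | Path] = None,
    control_every: int = 10,
) -> tuple[pd.DataFrame, SurrogateBatch]:
    """Dataset-skeleton generator: ``n_per_variety`` seed records per
    variety, organized into whole batches of ``seeds_per_batch`` seeds,
    each batch assigned one treatment cell (every ``control_every``-th
    batch is an untreated control).  Returns the records table and the
    paired (image, sequence, target) arrays; optionally writes
    ``records.csv``, ``arrays.npz`` and ``manifest.json``.
    """
    if not varieties:
        raise ValueError("need at least one variety")
    noiseless = noise == "none"
    design = design or FactorialDesign()
    img_spec = image_spec or ImageSpec(noise_level=0.0 if noiseless else 0.02)
    seq_spec = sequence_spec or SequenceSpec(noise_level=0.0 if noiseless else 0.02)
    cells = [c for c in enumerate_design(design) if c is not None]

    ss = np.random.SeedSequence(rng_seed).spawn(3)
    pheno_rng = np.random.default_rng(ss[0])
    img_rng = np.random.default_rng(ss[1])
    seq_rng = np.random.default_rng(ss[2])

    rows = []
    images = []
    sequences = []
    targets = []
    batch_ids = []
    for v_idx, profile in enumerate(varieties):
        order = pheno_rng.permutation(len(cells))
        batch_idx = 0
        remaining = n_per_variety
        while remaining > 0:
            n = min(seeds_per_batch, remaining)
            is_control = control_every > 0 and batch_idx % control_every == control_every - 1
            cell = None if is_control else cells[order[batch_idx % len(cells)]]
            bid = f"{profile.name}-b{batch_idx:03d}"
            dose = effective_dose(cell, profile, mech)
            seq = render_sequence(seq_spec, cell, seq_rng, mech)
            dg, _ = dose_response(dose, profile)
            p = float(np.clip((profile.control_germination_pct + dg) / 100.0, 0.0, 1.0))
            if not noiseless and profile.dispersion > 0:
                from .phenotype import _replicate_probability

                p = _replicate_probability(p, profile.dispersion, pheno_rng)
            for _ in range(n):
                latent = sample_latent(img_rng, v_idx, len(varieties))
                img = render_seed_image(img_spec, latent, img_rng)
                tvec = _record_targets(profile, dose, latent, pheno_rng, noiseless)
                germinated = 1 if (noiseless or pheno_rng.random() < p) else 0
                row = {
                    "variety": profile.name,
                    "batch_id": bid,
                    "cell": "control" if cell is None else f"c{order[batch_idx % len(cells)]:03d}",
                    "treated": cell is not None,
                    "field_strength_mT": 0.0 if cell is None else cell.field_strength_mT,
                    "frequency_Hz": 0.0 if cell is None else cell.frequency_Hz,
                    "duration_s": 0.0 if cell is None else cell.duration_s,
                    "voltage_amplitude_V": 0.0 if cell is None else cell.voltage_amplitude_V,
                    "pulse_width_ms": 0.0 if cell is None else cell.pulse_width_ms,
                    "duty_cycle_pct": 0.0 if cell is None else cell.duty_cycle_pct,
                    "dose": dose,
                    "germinated": germinated,
                    "latent_length": latent["length"],
                    "latent_width": latent["width"],
                    "latent_hue": latent["hue"],
                    "latent_response": (dg / profile.delta_g_max) if profile.delta_g_max else 0.0,
                }
                row.update({f"target_{name}": v for name, v in zip(TARGET_NAMES, tvec)})
                rows.append(row)
                images.append((img * 255).astype(np.uint8))
                sequences.append(seq.astype(np.float32))
                targets.append(tvec)
                batch_ids.append(bid)
            remaining -= n
            batch_idx += 1

    records = pd.DataFrame(rows)
    batch = SurrogateBatch(
        images=np.stack(images).astype(np.float32) / 255.0,
        sequences=np.stack(sequences),
        targets=np.stack(targets),
        batch_ids=np.asarray(batch_ids),
        records=records[["batch_id", "variety", "cell"]].copy(),
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        csv_path = out / "records.csv"
        try:
            records.to_csv(csv_path, index=False, float_format="%.8g")
            np.savez_compressed(
                out / "arrays.npz",
                images=np.stack(images),
                sequences=batch.sequences,
                targets=batch.targets,
                batch_ids=batch.batch_ids,
            )
            digest = hashlib.sha256(csv_path.read_bytes()).hexdigest()
            (out / "manifest.json").write_text(
                json.dumps(
                    {
                        "n_records": len(records),
                        "n_varieties": len(varieties),
                        "rng_seed": rng_seed,
                        "noise": noise,
                        "records_sha256": digest,
                    },
                    indent=2,
                )
            )
        except OSError:
            for name in ("records.csv", "arrays.npz", "manifest.json"):
                (out / name).unlink(missing_ok=True)
            raise
    return records, batch
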