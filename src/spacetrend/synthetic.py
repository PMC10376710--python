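"""Seeded synthetic cohorts with planted trend archetypes.

Real spaceflight biomarker panels of this kind are access-restricted, so the
package ships a generator that emulates their structure: a cohort of subjects
observed at irregular visit days spanning roughly -180 d to +225 d around
launch, a panel of measurement annotations per subject, visit dropout, and a
handful of planted temporal archetypes (in-flight rise persisting post-flight,
in-flight rise reverting at return, landing spike or dip, flat noise).
Blocks of subjects share archetype assignments so that the cross-subject
network stage has recoverable community structure, and every planted
(subject, measurement) pair carries a ground-truth label for benchmarking.

Default cohort dimensions mirror the study conditions the pipeline targets:
27 subjects and 264 measurement annotations, visits every ~15 days with
jitter, 10% visit dropout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from spacetrend.grid import MISSION_GRID_DAYS, TimeGrid

ARCHETYPE_NAMES = (
    "flight_rise_persist",
    "flight_rise_revert",
    "landing_spike",
    "landing_dip",
    "flat",
)

#: Bins (by day label) each archetype displaces from baseline.
_AFFECTED: dict[str, tuple[float, ...]] = {
    "flight_rise_persist": (33.0, 82.0, 132.0, 165.0, 195.0, 225.0),
    "flight_rise_revert": (33.0, 82.0, 132.0),
    "landing_spike": (165.0,),
    "landing_dip": (165.0,),
    "flat": (),
}

#: Trend class the classifier is expected to assign at high signal-to-noise.
_EXPECTED_CLASS: dict[str, str | None] = {
    "flight_rise_persist": "lag",
    "flight_rise_revert": "lag",
    "landing_spike": "spike_max",
    "landing_dip": "spike_min",
    "flat": None,
}

CSV_COLUMNS = ("subject_id", "measurement_id", "fluid", "time_days", "value", "units")


@dataclass(frozen=True)
class ArchetypeSpec:
    """A planted temporal shape.

    amplitude and noise_sd are in the (arbitrary) raw intensity units of the
    measurement; affected_bins defaults to the canonical set for the named
    archetype.
    """

    name: str
    amplitude: float = 3.0
    noise_sd: float = 1.0
    affected_bins: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.name not in ARCHETYPE_NAMES:
            raise ValueError(f"unknown archetype {self.name!r}")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.affected_bins is not None:
            unknown = set(self.affected_bins) - set(MISSION_GRID_DAYS)
            if unknown:
                raise ValueError(f"affected_bins not on the mission grid: {sorted(unknown)}")

    @property
    def expected_class(self) -> str | None:
        return _EXPECTED_CLASS[self.name]


def archetype_template(spec: ArchetypeSpec, grid: TimeGrid | None = None) -> np.ndarray:
    """Noise-free bin-level template of an archetype, length ``grid.n_bins``.

    The template is the additive displacement from the subject's baseline
    level: e.g. a landing spike of amplitude a is zero everywhere except +a
    at the 165 d bin, and a landing dip is -a there.
    """
    grid = grid or TimeGrid()
    affected = _AFFECTED[spec.name] if spec.affected_bins is None else spec.affected_bins
    sign = -1.0 if spec.name == "landing_dip" else 1.0
    template = np.zeros(grid.n_bins)
    for day in affected:
        template[list(grid.labels).index(day)] = sign * spec.amplitude
    return template


@dataclass
class GroundTruth:
    """Planted labels for a synthetic cohort.

    planted maps (subject_id, measurement_id) to the expected trend-class
    family ("lag", "spike_max", "spike_min"); pairs generated as flat noise
    are absent.  blocks maps each subject to its community label.
    """

    planted: dict[tuple[str, str], str] = field(default_factory=dict)
    blocks: dict[str, int] = field(default_factory=dict)
    archetypes: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": [{"subject_id": s, "measurement_id": m, "class": c}
                        for (s, m), c in sorted(self.planted.items())],
            "archetypes": [{"subject_id": s, "measurement_id": m, "archetype": a}
                           for (s, m), a in sorted(self.archetypes.items())],
            "blocks": dict(sorted(self.blocks.items())),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted={(r["subject_id"], r["measurement_id"]): r["class"]
                     for r in payload["planted"]},
            blocks={k: int(v) for k, v in payload["blocks"].items()},
            archetypes={(r["subject_id"], r["measurement_id"]): r["archetype"]
                        for r in payload.get("archetypes", [])},
        )


@dataclass(frozen=True)
class CohortConfig:
    """Everything that determines a synthetic cohort, including the seed.

    assignment maps (block index, measurement_id) to the archetype planted
    for all subjects of that block; measurements absent from the map are flat
    noise at background_noise_sd.  Subjects are split into ``n_blocks``
    near-equal contiguous blocks.
    """

    n_subjects: int = 27
    n_measurements: int = 264
    n_blocks: int = 3
    assignment: Mapping[tuple[int, str], ArchetypeSpec] = field(default_factory=dict)
    sampling_interval_days: float = 15.0
    sampling_jitter_days: float = 4.0
    dropout: float = 0.10
    baseline_level: float = 10.0
    background_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0 or self.n_measurements < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    def subject_ids(self) -> list[str]:
        return [f"S{i:02d}" for i in range(1, self.n_subjects + 1)]

    def measurement_ids(self) -> list[str]:
        return [f"M{i:03d}" for i in range(1, self.n_measurements + 1)]

    def block_of(self, subject_index: int) -> int:
        return subject_index * self.n_blocks // max(self.n_subjects, 1)


_FLUIDS = ("serum", "urine", "plasma", "immune")


def default_assignment(
    config: CohortConfig,
    planted_fraction: float = 0.30,
    amplitude: float = 3.0,
    noise_sd: float = 1.0,
) -> dict[tuple[int, str], ArchetypeSpec]:
    """Block-structured archetype assignment covering the archetype menu.

    The first ``planted_fraction`` of measurements are planted; each block
    cycles through the non-flat archetypes with a block-specific phase so
    that blocks have distinct archetype profiles across the panel.
    """
    menu = [a for a in ARCHETYPE_NAMES if a != "flat"]
    n_planted = int(round(planted_fraction * config.n_measurements))
    assignment: dict[tuple[int, str], ArchetypeSpec] = {}
    for j, mid in enumerate(config.measurement_ids()[:n_planted]):
        for b in range(config.n_blocks):
            name = menu[(j + b) % len(menu)]
            assignment[(b, mid)] = ArchetypeSpec(name, amplitude=amplitude, noise_sd=noise_sd)
    return assignment


def two_block_config(
    n_subjects: int = 12,
    n_measurements: int = 8,
    amplitude: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> CohortConfig:
    """Small two-block cohort with disjoint archetype sets per block.

    Block 0 carries persisting in-flight rises, block 1 landing spikes, on
    every measurement — the sharpest possible community structure, used for
    planted-block recovery benchmarks.
    """
    config = CohortConfig(
        n_subjects=n_subjects, n_measurements=n_measurements, n_blocks=2,
        seed=seed, **kwargs,
    )
    assignment = {}
    for mid in config.measurement_ids():
        assignment[(0, mid)] = ArchetypeSpec("flight_rise_persist", amplitude, noise_sd)
        assignment[(1, mid)] = ArchetypeSpec("landing_spike", amplitude, noise_sd)
    return replace(config, assignment=assignment)


def generate_cohort(
    config: CohortConfig, grid: TimeGrid | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate raw long-format records and their ground truth.

    Returns a DataFrame with columns (subject_id, measurement_id, fluid,
    time_days, value, units), one row per retained raw observation.  All
    randomness derives from ``config.seed``; identical configs produce
    identical output.
    """
    grid = grid or TimeGrid()
    rng = np.random.default_rng(config.seed)
    subjects = config.subject_ids()
    measurements = config.measurement_ids()
    truth = GroundTruth(blocks={s: config.block_of(i) for i, s in enumerate(subjects)})

    rows: list[tuple] = []
    for i, sid in enumerate(subjects):
        block = config.block_of(i)
        # per-subject visit days: jittered regular schedule across the window
        base_days = np.arange(grid.labels[0], grid.labels[-1] + 1e-9,
                              config.sampling_interval_days)
        days = base_days + rng.uniform(-config.sampling_jitter_days,
                                       config.sampling_jitter_days, size=len(base_days))
        days = days[(days >= grid.window[0]) & (days < grid.window[1])]
        bin_idx = grid.bin_indices(days)
        for j, mid in enumerate(measurements):
            spec = config.assignment.get((block, mid))
            if spec is None:
                template = np.zeros(grid.n_bins)
                noise_sd = config.background_noise_sd
            else:
                template = archetype_template(spec, grid)
                noise_sd = spec.noise_sd
                if spec.expected_class is not None:
                    truth.planted[(sid, mid)] = spec.expected_class
                    truth.archetypes[(sid, mid)] = spec.name
            keep = rng.random(len(days)) >= config.dropout
            noise = rng.normal(0.0, 1.0, size=len(days)) * noise_sd
            values = config.baseline_level + template[bin_idx] + noise
            fluid = _FLUIDS[j % len(_FLUIDS)]
            for day, value, k in zip(days, values, keep):
                if k:
                    rows.append((sid, mid, fluid, float(day), float(value), "au"))
    records = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return records, truth


def write_cohort(records: pd.DataFrame, path: str | Path) -> None:
    """Write records as the long-format cohort CSV (missing values empty)."""
    records.loc[:, CSV_COLUMNS].to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, validating row-by-row with line numbers on error."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file {path} missing columns: {sorted(missing)}")
    for col in ("time_days", "value"):
        raw = df[col].replace("", np.nan)
        converted = pd.to_numeric(raw, errors="coerce")
        bad = raw.notna() & converted.isna()
        if bad.any():
            # +2: one for the header, one for 1-based numbering
            lines = (df.index[bad] + 2).tolist()
            raise ValueError(
                f"non-numeric {col!r} in {path} at line(s) {lines[:10]}"
            )
        df[col] = converted
    return df.loc[:, CSV_COLUMNS]
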