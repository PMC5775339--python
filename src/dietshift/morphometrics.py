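"""Fish length reconstruction from otoliths and age-group assignment.

Otoliths (the digestion-resistant ear stones of fish) are often the only
identifiable fish remains in seabird regurgitates.  Within a species, fish
body length scales linearly with otolith length, so a per-species linear
regression recovers length; ordered length cutoffs then map lengths to age
classes (0+, 1, ..., >4).  Regression coefficients and cutoffs are supplied
by a YAML config — the package ships synthetic placeholder values users must
replace with species- and region-appropriate literature coefficients.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

AGE_LABELS = ("0+", "1", "2", "3", "4", ">4")

#: otoliths are read to 0.1 mm; pairs within this span likely share a fish
DEFAULT_PAIR_TOLERANCE = 0.3


@dataclass(frozen=True)
class OtolithRegression:
    """fish_length_mm = (intercept + slope * otolith_mm) * shrinkage_factor."""

    species: str
    intercept: float          # mm
    slope: float              # mm fish per mm otolith; must be positive
    valid_range: tuple[float, float]  # otolith mm interval the fit covers
    shrinkage_factor: float = 1.0     # 1.00-1.04 corrects frozen-material bias

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"{self.species}: slope must be positive")
        if not 1.0 <= self.shrinkage_factor <= 1.04:
            raise ValueError("shrinkage factor must lie in [1.00, 1.04]")
        if self.valid_range[0] >= self.valid_range[1]:
            raise ValueError("valid otolith range must be a proper interval")


@dataclass(frozen=True)
class AgeKey:
    """Ordered length cutoffs (mm) splitting a species into age classes.

    n cutoffs define n+1 classes labelled from the front of ``AGE_LABELS``;
    lengths below the first cutoff are 0+ by convention, above the last the
    oldest class.
    """

    species: str
    cutoffs: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValueError(f"{self.species}: cutoffs must strictly increase")
        if len(self.cutoffs) >= len(AGE_LABELS):
            raise ValueError("too many cutoffs for the age-label set")

    def classify(self, length_mm: float) -> str:
        idx = sum(length_mm > c for c in self.cutoffs)
        labels = AGE_LABELS[:len(self.cutoffs)] + (AGE_LABELS[-1],)
        return labels[idx]


class MorphometricsConfig:
    """Per-species regressions and age keys loaded from YAML."""

    def __init__(self, regressions: dict[str, OtolithRegression],
                 age_keys: dict[str, AgeKey]):
        self.regressions = regressions
        self.age_keys = age_keys

    def regression(self, species: str) -> OtolithRegression:
        try:
            return self.regressions[species]
        except KeyError:
            raise ValueError(f"no otolith regression for species {species!r}")

    def age_key(self, species: str) -> AgeKey:
        try:
            return self.age_keys[species]
        except KeyError:
            raise ValueError(f"no age key for species {species!r}")

    @classmethod
    def from_yaml(cls, path_or_stream) -> "MorphometricsConfig":
        if hasattr(path_or_stream, "read"):
            raw = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                raw = yaml.safe_load(fh)
        regs = {
            sp: OtolithRegression(
                species=sp, intercept=float(v["intercept_mm"]),
                slope=float(v["slope"]),
                valid_range=(float(v["otolith_min_mm"]),
                             float(v["otolith_max_mm"])),
                shrinkage_factor=float(v.get("shrinkage_factor", 1.0)),
            )
            for sp, v in (raw.get("regressions") or {}).items()
        }
        keys = {
            sp: AgeKey(sp, tuple(float(c) for c in cutoffs))
            for sp, cutoffs in (raw.get("age_cutoffs_mm") or {}).items()
        }
        return cls(regs, keys)

    @classmethod
    def placeholders(cls) -> "MorphometricsConfig":
        """The bundled synthetic placeholder config (replace for real use)."""
        ref = resources.files("dietshift.data") / "morphometrics_synthetic.yaml"
        return cls.from_yaml(ref.open())


def pair_otoliths(lengths, tolerance: float = DEFAULT_PAIR_TOLERANCE
                  ) -> list[float]:
    """Merge otolith measurements that likely came from the same fish.

    Greedy closest-first: repeatedly average the two closest remaining
    measurements while their gap is within ``tolerance`` mm; leftovers pass
    through unchanged.  Pairing only ever happens within one (sample, species)
    batch — callers must not mix batches.
    """
    remaining = [float(v) for v in lengths]
    paired: list[float] = []
    while len(remaining) >= 2:
        vals = sorted(range(len(remaining)), key=remaining.__getitem__)
        best = min(
            (abs(remaining[vals[i + 1]] - remaining[vals[i]]),
             vals[i], vals[i + 1])
            for i in range(len(vals) - 1)
        )
        gap, i, j = best
        if gap > tolerance:
            break
        a, b = remaining[i], remaining[j]
        for idx in sorted((i, j), reverse=True):
            remaining.pop(idx)
        paired.append((a + b) / 2.0)
    return paired + remaining


def estimate_length(otolith_mm: float, regression: OtolithRegression
                    ) -> tuple[float, bool]:
    """Fish length (mm) from otolith length; flags out-of-range extrapolation."""
    if otolith_mm <= 0:
        raise ValueError("otolith length must be positive")
    lo, hi = regression.valid_range
    length = (regression.intercept + regression.slope * otolith_mm) \
        * regression.shrinkage_factor
    return float(length), not (lo <= otolith_mm <= hi)


def assign_age(length_mm: float, species: str, key: AgeKey | MorphometricsConfig,
               capture_date: dt.date | None = None,
               spawning_window: tuple[dt.date, dt.date] | None = None,
               ) -> tuple[str, tuple[int, int] | None]:
    """Age class from length; for 0+ fish, days elapsed since spawning.

    ``spawning_window`` is the (start, end) of the species' spawning period;
    for a 0+ fish with a capture date the returned pair is days since the
    window's end and since its start (an elapsed-time envelope).  Defaults to
    the February-April window of Atlantic spawners in the capture year.
    """
    age_key = key.age_key(species) if isinstance(key, MorphometricsConfig) \
        else key
    cls = age_key.classify(length_mm)
    elapsed = None
    if cls == "0+" and capture_date is not None:
        if spawning_window is None:
            spawning_window = (dt.date(capture_date.year, 2, 15),
                               dt.date(capture_date.year, 4, 1))
        start, end = spawning_window
        elapsed = ((capture_date - end).days, (capture_date - start).days)
    return cls, elapsed


def morphometrics_table(df: pd.DataFrame, config: MorphometricsConfig,
                        pair_tolerance: float = DEFAULT_PAIR_TOLERANCE
                        ) -> pd.DataFrame:
    """Per-fish lengths and ages from a (sample_id, species, otolith_mm) table.

    Otoliths are paired within each (sample_id, species) batch; species
    without a configured regression are passed over with ``fish_length_mm``
    empty.
    """
    rows = []
    for (sid, species), grp in df.groupby(["sample_id", "species"], sort=False):
        fish = pair_otoliths(grp["otolith_mm"].tolist(), pair_tolerance)
        for oto in fish:
            row = {"sample_id": sid, "species": species, "otolith_mm": oto}
            try:
                reg = config.regression(species)
            except ValueError:
                rows.append(row)
                continue
            length, extrapolated = estimate_length(oto, reg)
            row["fish_length_mm"] = length
            row["extrapolated"] = extrapolated
            try:
                row["age_class"] = config.age_key(species).classify(length)
            except ValueError:
                pass
            rows.append(row)
    return pd.DataFrame(rows)
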