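"""Parkes consensus error grid (Type 1 diabetes) zone classification.

The Parkes grid partitions the (reference, meter) glucose plane, both axes
0-550 mg/dL, into risk zones A-E graded by the clinical consequence of the
measurement error: A "no effect on clinical action", B "altered clinical
results, little or no effect on clinical outcome", C "altered clinical
action, likely to affect clinical outcome", D "could have significant
clinical risk", E "could have dangerous consequences".

The zone boundaries are piecewise-linear polylines between published vertex
coordinates (shipped in ``data/parkes_type1.json``; Pfutzner et al. 2013).
Classification works on the nested "no worse than" regions

    S_A c S_B c S_C c S_D c domain,

where ``S_k`` is bounded above by the upper k/k+1 boundary (a function of
reference) and on the right by the lower k/k+1 boundary (a function of
meter).  A point's zone is the first region that contains it, so boundary
points deterministically resolve to the lower-risk zone.  Explicit zone
polygons (for plotting and for independent point-in-polygon checks) are
built from the same boundaries with shapely.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

from .accuracy_stats import AccuracySummary
from .measurements_io import ConditionKey

ZONES = ("A", "B", "C", "D", "E")
#: boundary keys in increasing-risk order; "AB" separates zone A from B, etc.
UPPER_KEYS = ("AB", "BC", "CD", "DE")
LOWER_KEYS = ("AB", "BC", "CD")  # no E zone below the identity line (Type 1)


class GridValidationError(ValueError):
    """The zone configuration does not form a valid partition."""


@dataclass
class ZonePolygonSet:
    """Zone boundaries of a consensus error grid plus derived polygons.

    ``upper`` maps boundary key -> (n, 2) vertex array in (reference, meter)
    order; ``lower`` boundaries are monotone in *meter*, so they are stored
    as given in (reference, meter) but evaluated as reference = g(meter).
    """

    grid_name: str
    upper: dict[str, np.ndarray]
    lower: dict[str, np.ndarray]
    domain: tuple[float, float] = (0.0, 550.0)
    notes: str = ""
    _polygons: dict | None = field(default=None, repr=False, compare=False)

    # -- boundary evaluation ----------------------------------------------

    def upper_meter_at(self, key: str, reference: np.ndarray) -> np.ndarray:
        """Meter value of an upper boundary at given reference values.

        Beyond the last vertex the boundary has left the domain through the
        top, so it is extended at the domain maximum (every in-domain point
        is then on the safe side).
        """
        v = self.upper[key]
        return np.interp(reference, v[:, 0], v[:, 1], right=self.domain[1])

    def lower_reference_at(self, key: str, meter: np.ndarray) -> np.ndarray:
        """Reference value of a lower boundary at given meter values."""
        v = self.lower[key]
        # stored as (reference, meter); evaluate reference as function of meter
        return np.interp(meter, v[:, 1], v[:, 0], right=self.domain[1])

    # -- classification ----------------------------------------------------

    def classify(
        self,
        reference: np.ndarray | float,
        meter: np.ndarray | float,
        clamp: bool = False,
    ) -> np.ndarray:
        """Vectorized zone labels for (reference, meter) pairs.

        Out-of-domain points raise unless ``clamp=True``, in which case they
        are clamped onto the domain edge with a warning (a meter reading of
        600 mg/dL carries the same clinical meaning as 550 here).
        """
        ref = np.atleast_1d(np.asarray(reference, dtype=float))
        met = np.atleast_1d(np.asarray(meter, dtype=float))
        ref, met = np.broadcast_arrays(ref, met)
        lo, hi = self.domain
        out_of_domain = (ref < lo) | (ref > hi) | (met < lo) | (met > hi)
        if out_of_domain.any():
            if not clamp:
                raise ValueError(
                    f"{int(out_of_domain.sum())} point(s) outside the "
                    f"[{lo}, {hi}] mg/dL grid domain"
                )
            warnings.warn(
                f"clamping {int(out_of_domain.sum())} out-of-domain point(s) "
                "onto the error-grid domain edge",
                stacklevel=2,
            )
            ref = np.clip(ref, lo, hi)
            met = np.clip(met, lo, hi)

        zone = np.full(ref.shape, "E", dtype="<U1")
        unassigned = np.ones(ref.shape, dtype=bool)
        for label, key in zip(("A", "B", "C"), ("AB", "BC", "CD")):
            inside = (
                unassigned
                & (met <= self.upper_meter_at(key, ref))
                & (ref <= self.lower_reference_at(key, met))
            )
            zone[inside] = label
            unassigned &= ~inside
        # S_D has an upper boundary only: no E zone below the identity line
        inside = unassigned & (met <= self.upper_meter_at("DE", ref))
        zone[inside] = "D"
        return zone

    def classify_point(self, reference: float, meter: float, clamp: bool = False) -> str:
        """Zone label of a single (reference, meter) pair."""
        return str(self.classify(reference, meter, clamp=clamp)[0])

    # -- polygon view -------------------------------------------------------

    def zone_polygons(self) -> dict[str, shapely.Geometry]:
        """Explicit zone polygons (possibly multipart) partitioning the domain.

        Built by intersecting/differencing the nested safe regions, entirely
        independent of the boundary-function classifier above, which makes
        them usable as a cross-check as well as for plotting.
        """
        if self._polygons is None:
            lo, hi = self.domain
            box = Polygon([(lo, lo), (hi, lo), (hi, hi), (lo, hi)])

            def below(vts: np.ndarray) -> Polygon:
                # region under a polyline meter = f(reference)
                pts = [(lo, lo), (hi, lo)]
                if vts[-1, 0] < hi:  # boundary exits through the top
                    pts.append((hi, hi))
                pts.extend((float(x), float(y)) for x, y in vts[::-1])
                return Polygon(pts).intersection(box)

            def left_of(vts: np.ndarray) -> Polygon:
                # region left of a polyline reference = g(meter)
                pts = [(lo, lo)]
                pts.extend((float(x), float(y)) for x, y in vts)
                if vts[-1, 1] < hi:  # boundary exits through the right edge
                    pts.append((hi, hi))
                pts.append((lo, hi))
                return Polygon(pts).intersection(box)

            safe = {}
            for label, key in zip(("A", "B", "C"), ("AB", "BC", "CD")):
                safe[label] = below(self.upper[key]).intersection(
                    left_of(self.lower[key])
                )
            safe["D"] = below(self.upper["DE"])
            polys = {"A": safe["A"]}
            for outer, inner in (("B", "A"), ("C", "B"), ("D", "C")):
                polys[outer] = safe[outer].difference(safe[inner])
            polys["E"] = box.difference(safe["D"])
            self._polygons = polys
        return self._polygons

    # -- validation ---------------------------------------------------------

    def validate(self, lattice_step: float = 25.0) -> None:
        """Check partition and identity-line invariants; raise on failure."""
        lo, hi = self.domain
        grid = np.arange(lo, hi + 1e-9, 1.0)
        # boundary nesting: upper boundaries strictly ordered away from identity
        prev = None
        for key in UPPER_KEYS:
            cur = self.upper_meter_at(key, grid)
            if prev is not None and np.any(cur < prev):
                raise GridValidationError(f"upper boundary {key} crosses its inner neighbour")
            prev = cur
        prev = None
        for key in LOWER_KEYS:
            cur = self.lower_reference_at(key, grid)
            if prev is not None and np.any(cur < prev):
                raise GridValidationError(f"lower boundary {key} crosses its inner neighbour")
            prev = cur
        # identity line entirely zone A
        ident = np.linspace(lo, hi, 221)
        if not np.all(self.classify(ident, ident) == "A"):
            raise GridValidationError("identity line is not entirely in zone A")
        # coverage lattice: function-based and polygon-based classification agree
        xs = np.arange(lo, hi + 1e-9, lattice_step)
        rx, mx = np.meshgrid(xs, xs)
        rx, mx = rx.ravel(), mx.ravel()
        fast = self.classify(rx, mx)
        polys = self.zone_polygons()
        assigned = np.zeros(rx.shape, dtype=bool)
        for z in ZONES:
            covered = shapely.covers(polys[z], shapely.points(rx, mx))
            if not np.all(covered[fast == z]):
                raise GridValidationError(
                    f"zone {z} polygon does not cover all points classified {z}"
                )
            assigned |= covered
        if not assigned.all():
            raise GridValidationError("zone polygons leave gaps on the validation lattice")


@dataclass
class ZoneResult:
    """Zone assignment for one device/condition average point."""

    device_model: str
    condition: ConditionKey
    reference_mgdl: float
    meter_mgdl: float
    zone: str
    meter_sd_mgdl: float | None = None  # +/- 1 SD interval for plotting


def load_zone_polygons(config: str | Path | None = None) -> ZonePolygonSet:
    """Load and validate a zone-boundary configuration.

    With no argument, the packaged Parkes Type-1 consensus grid is loaded.
    A configuration missing a boundary, or whose boundaries fail the
    partition/identity invariants, raises :class:`GridValidationError`.
    """
    if config is None:
        raw = json.loads(
            resources.files("glucompare.data").joinpath("parkes_type1.json").read_text()
        )
    else:
        raw = json.loads(Path(config).read_text())
    for section, keys in (("upper_boundaries", UPPER_KEYS), ("lower_boundaries", LOWER_KEYS)):
        if section not in raw:
            raise GridValidationError(f"grid config missing section {section!r}")
        missing = [k for k in keys if k not in raw[section]]
        if missing:
            raise GridValidationError(
                f"grid config {section} missing boundary: {', '.join(missing)}"
            )
    grid = ZonePolygonSet(
        grid_name=raw.get("grid_name", "unnamed"),
        upper={k: np.asarray(v, dtype=float) for k, v in raw["upper_boundaries"].items()},
        lower={k: np.asarray(v, dtype=float) for k, v in raw["lower_boundaries"].items()},
        domain=tuple(raw.get("domain", (0.0, 550.0))),
        notes=raw.get("notes", ""),
    )
    grid.validate()
    return grid


def classify_point(point: tuple[float, float], zones: ZonePolygonSet) -> str:
    """Zone label for a single (reference, meter) pair; raises out of domain."""
    return zones.classify_point(point[0], point[1])


def classify_condition_averages(
    summaries: Iterable[AccuracySummary],
    zones: ZonePolygonSet,
) -> list[ZoneResult]:
    """Zone the per-(device, condition) average points.

    Each point is (mean reference, mean meter) pooled across days, with the
    meter +/- 1 SD interval carried for plotting.  Summaries with no pooled
    means (empty cells) are skipped with a warning.
    """
    results = []
    for s in summaries:
        if s.mean_meter_mgdl is None or s.mean_reference_mgdl is None:
            warnings.warn(
                f"skipping {s.device_model} @ {s.condition.label()}: no pooled means",
                stacklevel=2,
            )
            continue
        zone = zones.classify_point(s.mean_reference_mgdl, s.mean_meter_mgdl, clamp=True)
        results.append(
            ZoneResult(
                device_model=s.device_model,
                condition=s.condition,
                reference_mgdl=s.mean_reference_mgdl,
                meter_mgdl=s.mean_meter_mgdl,
                zone=zone,
                meter_sd_mgdl=s.sd_meter_mgdl,
            )
        )
    return results
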