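"""Physical arithmetic of a fixed microwell partition array.

A molded-array dPCR consumable partitions the reaction into a rectangular
grid of microwells of fixed, injection-molded dimensions (nominally
65 × 82 × 97 µm, 517 pL, 20,000 wells per array).  Because the geometry is
fixed, everything about partition volume, total analyzed volume, sample
utilization, subsampling error and the minimal detectable allele fraction is
deterministic arithmetic on the array geometry.  This module holds that
arithmetic; it draws no random numbers and touches no images.

Units
-----
well dimensions   µm
partition volume  pL   (1 pL = 10³ µm³)
array volume      µL   (1 µL = 10⁶ pL)
concentration     copies/µL (C_p/µL)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidInputError

#: cubic micrometres per picolitre
UM3_PER_PL = 1_000.0
#: picolitres per microlitre
PL_PER_UL = 1_000_000.0


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


@dataclass(frozen=True)
class WellDimensions:
    """Inner dimensions of one microwell, in µm."""

    x: float = 65.0
    y: float = 82.0
    z: float = 97.0

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"well dimension {name} must be > 0")

    @property
    def volume_pl(self) -> float:
        """Well volume in pL."""
        return self.x * self.y * self.z / UM3_PER_PL


@dataclass(frozen=True)
class ToleranceSpec:
    """Manufacturing dimensional tolerance: planar applies to x and y, height to z."""

    planar: float = 0.1
    height: float = 1.0

    def __post_init__(self) -> None:
        if self.planar < 0 or self.height < 0:
            raise InvalidInputError("tolerances must be non-negative")


@dataclass(frozen=True)
class ArrayGeometry:
    """Layout of one partition array: well dimensions, grid shape and pitch.

    ``pitch_x``/``pitch_y`` are centre-to-centre spacings in µm and must be at
    least the corresponding well dimension (wells cannot overlap).
    """

    wells: WellDimensions = WellDimensions()
    rows: int = 100
    cols: int = 200
    pitch_x: float = 91.0
    pitch_y: float = 107.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise InvalidInputError("rows and cols must be >= 1")
        if self.pitch_x < self.wells.x or self.pitch_y < self.wells.y:
            raise InvalidInputError("pitch must be >= well dimension")

    @property
    def n_partitions(self) -> int:
        return self.rows * self.cols

    @property
    def nominal_volume_pl(self) -> float:
        return self.wells.volume_pl


#: the default consumable: 20,000 wells of 65 × 82 × 97 µm
DEFAULT_GEOMETRY = ArrayGeometry()


@dataclass(frozen=True)
class UtilizationReport:
    """How much of the loaded sample is actually analyzed."""

    analyzed_volume_ul: float
    input_volume_ul: float
    fill_success: float
    utilization_pct: float


@dataclass(frozen=True)
class SubsamplingReport:
    """Statistics of detecting a fixed number of input copies after subsampling."""

    expected_copies: int
    analyzed_fraction: float
    expected_detected: float
    cv: float


def partition_volume(dims: WellDimensions) -> float:
    """Volume of one partition in pL: x·y·z µm³ / 10³."""
    return dims.volume_pl


def array_volume(geom: ArrayGeometry) -> float:
    """Total analyzed volume of one array in µL (n_partitions × well volume)."""
    return geom.n_partitions * geom.nominal_volume_pl / PL_PER_UL


def worst_case_volume_variation(dims: WellDimensions, tol: ToleranceSpec) -> float:
    """Worst-case relative volume change, in percent, under dimensional tolerances.

    Grows/shrinks every dimension by its full tolerance and takes the larger of
    the two relative deviations of the product x·y·z.  The grow and shrink
    cases differ only in the quadratic cross terms, so the result is the
    dominant linear sum δx/x + δy/y + δz/z plus small corrections.
    """
    if tol.planar >= min(dims.x, dims.y) or tol.height >= dims.z:
        raise InvalidInputError("tolerance must be smaller than the dimension")
    nominal = dims.x * dims.y * dims.z
    grow = (dims.x + tol.planar) * (dims.y + tol.planar) * (dims.z + tol.height)
    shrink = (dims.x - tol.planar) * (dims.y - tol.planar) * (dims.z - tol.height)
    return 100.0 * max(grow / nominal - 1.0, 1.0 - shrink / nominal)


def utilization(analyzed_volume_ul: float, fill_success: float,
                input_volume_ul: float) -> UtilizationReport:
    """Utilization = 100 · analyzed volume · fill success / input volume."""
    if input_volume_ul <= 0:
        raise InvalidInputError("input volume must be > 0")
    if not 0.0 <= fill_success <= 1.0:
        raise InvalidInputError("fill_success must lie in [0, 1]")
    pct = 100.0 * analyzed_volume_ul * fill_success / input_volume_ul
    return UtilizationReport(analyzed_volume_ul, input_volume_ul, fill_success, pct)


def sample_utilization(geom: ArrayGeometry, fill_success: float,
                       input_volume_ul: float) -> UtilizationReport:
    """Utilization of an input sample loaded onto one array."""
    return utilization(array_volume(geom), fill_success, input_volume_ul)


def subsampling_error(expected_copies: int, analyzed_fraction: float) -> SubsamplingReport:
    """Detection statistics when only a fraction of the input sample is analyzed.

    The detected count of ``m`` input copies, each independently captured with
    probability ``f`` (the analyzed fraction), is Binomial(m, f):
    mean m·f, CV = sqrt((1 − f) / (m·f)).  The whole-sample case f = 1 has
    zero subsampling error by construction.
    """
    if expected_copies < 1:
        raise InvalidInputError("expected_copies must be >= 1")
    if not 0.0 < analyzed_fraction <= 1.0:
        raise InvalidInputError("analyzed_fraction must lie in (0, 1]")
    m, f = expected_copies, analyzed_fraction
    cv = math.sqrt((1.0 - f) / (m * f))
    return SubsamplingReport(m, f, m * f, cv)


def min_detectable_fraction(geom: ArrayGeometry, reference_conc: float,
                            min_positive_partitions: int = 3) -> float:
    """Smallest target:reference fraction (percent) detectable on one array.

    Detection rule: the expected number of target copies in the analyzed
    volume must reach ``min_positive_partitions`` (default 3, a common dPCR
    convention).  Returns 100 · k_min / (reference_conc · analyzed volume).
    """
    if reference_conc <= 0:
        raise InvalidInputError("reference concentration must be > 0")
    if min_positive_partitions < 1:
        raise InvalidInputError("min_positive_partitions must be >= 1")
    return 100.0 * min_positive_partitions / (reference_conc * array_volume(geom))
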