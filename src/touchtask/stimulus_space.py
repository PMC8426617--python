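"""Multidimensional stimulus feature space and constrained stimulus sampling.

Stimuli are symbolic descriptors: one value label per feature dimension.
Each dimension designates one *neutral* value that is never rewarded; an
object that is neutral in every dimension is special (choosing it aborts a
trial).  The default space has four dimensions with cardinalities
(9, 8, 11, 9), giving 7,128 unique objects.

Colors are modeled as points on a fixed-chroma circle in the CIELAB a*b*
plane at equal hue increments, which makes all adjacent-pair Lab distances
equal by construction.
"""

from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
import yaml

__all__ = [
    "Dimension",
    "FeatureSpace",
    "Descriptor",
    "LabColor",
    "FeatureSpaceError",
    "FeasibilityError",
    "build_feature_space",
    "default_feature_space",
    "enumerate_objects",
    "make_color_palette",
    "lab_to_srgb",
    "palette_to_csv",
    "neutral_dimension_count",
    "shared_feature_count",
    "sample_target",
    "sample_search_array",
    "sample_learning_array",
    "load_feature_space",
    "save_feature_space",
    "descriptor_to_str",
    "descriptor_from_str",
]

#: A stimulus descriptor: one value label per dimension, in dimension order.
Descriptor = tuple[str, ...]


class FeatureSpaceError(ValueError):
    """Invalid feature-space definition or descriptor."""


class FeasibilityError(ValueError):
    """A sampling request cannot be satisfied by the space."""


@dataclass(frozen=True)
class Dimension:
    """One feature dimension: an ordered set of value labels plus its neutral value."""

    name: str
    values: tuple[str, ...]
    neutral: str

    def __post_init__(self) -> None:
        if not self.name:
            raise FeatureSpaceError("dimension name must be non-empty")
        if len(self.values) < 1:
            raise FeatureSpaceError(f"dimension {self.name!r}: needs at least one value")
        if len(set(self.values)) != len(self.values):
            raise FeatureSpaceError(f"dimension {self.name!r}: duplicate value labels")
        if self.neutral not in self.values:
            raise FeatureSpaceError(
                f"dimension {self.name!r}: neutral value {self.neutral!r} "
                "is not a member of the value list"
            )

    @property
    def cardinality(self) -> int:
        return len(self.values)

    @property
    def non_neutral_values(self) -> tuple[str, ...]:
        return tuple(v for v in self.values if v != self.neutral)


@dataclass(frozen=True)
class FeatureSpace:
    """An ordered collection of dimensions defining the combinatorial object set."""

    dimensions: tuple[Dimension, ...]

    def __post_init__(self) -> None:
        if len(self.dimensions) == 0:
            raise FeatureSpaceError("feature space needs at least one dimension")
        names = [d.name for d in self.dimensions]
        if len(set(names)) != len(names):
            raise FeatureSpaceError("duplicate dimension names")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.dimensions)

    @property
    def n_dimensions(self) -> int:
        return len(self.dimensions)

    @property
    def cardinalities(self) -> tuple[int, ...]:
        return tuple(d.cardinality for d in self.dimensions)

    @property
    def size(self) -> int:
        return math.prod(self.cardinalities)

    @property
    def neutral_descriptor(self) -> Descriptor:
        return tuple(d.neutral for d in self.dimensions)

    def index(self, dimension_name: str) -> int:
        for i, d in enumerate(self.dimensions):
            if d.name == dimension_name:
                return i
        raise FeatureSpaceError(f"unknown dimension {dimension_name!r}")

    def dimension(self, dimension_name: str) -> Dimension:
        return self.dimensions[self.index(dimension_name)]

    def contains(self, descriptor: Sequence[str]) -> bool:
        if len(descriptor) != self.n_dimensions:
            return False
        return all(v in d.values for v, d in zip(descriptor, self.dimensions))

    def validate_descriptor(self, descriptor: Sequence[str]) -> Descriptor:
        if not self.contains(descriptor):
            raise FeatureSpaceError(f"descriptor {descriptor!r} is not in this space")
        return tuple(descriptor)


def build_feature_space(spec: Iterable[dict]) -> FeatureSpace:
    """Build a validated :class:`FeatureSpace` from dimension definitions.

    ``spec`` is an iterable of mappings with keys ``name``, ``values``
    and ``neutral``.
    """
    dims = []
    for entry in spec:
        try:
            dims.append(
                Dimension(
                    name=str(entry["name"]),
                    values=tuple(str(v) for v in entry["values"]),
                    neutral=str(entry["neutral"]),
                )
            )
        except KeyError as exc:
            raise FeatureSpaceError(f"dimension definition missing key {exc}") from exc
    return FeatureSpace(dimensions=tuple(dims))


#: Default dimension definitions: cardinalities (9, 8, 11, 9) with the
#: neutral set {spherical body, gray color, straight blunt arms, uniform pattern}.
DEFAULT_DIMENSIONS: tuple[dict, ...] = (
    {
        "name": "body_shape",
        "values": [
            "spherical", "pyramidal", "oblong", "cubic", "cylindrical",
            "conical", "toroidal", "stellate", "biconic",
        ],
        "neutral": "spherical",
    },
    {
        "name": "color",
        "values": ["gray", "red", "orange", "yellow", "green", "cyan", "blue", "magenta"],
        "neutral": "gray",
    },
    {
        "name": "arm_type",
        "values": [
            "straight_blunt", "straight_pointed", "curved_blunt", "curved_pointed",
            "forked", "clubbed", "tapered", "knobbed", "spiraled", "feathered",
            "segmented",
        ],
        "neutral": "straight_blunt",
    },
    {
        "name": "surface_pattern",
        "values": [
            "uniform", "striped", "dotted", "checkered", "hatched",
            "waved", "honeycomb", "swirled", "gradient",
        ],
        "neutral": "uniform",
    },
)


def default_feature_space() -> FeatureSpace:
    """The default 4-dimensional space with cardinalities (9, 8, 11, 9)."""
    return build_feature_space(DEFAULT_DIMENSIONS)


def enumerate_objects(space: FeatureSpace) -> Iterator[Descriptor]:
    """Yield every descriptor in deterministic lexicographic order.

    Dimension order is as declared; value order within a dimension is as
    declared.  The number of descriptors equals the product of the
    dimension cardinalities.
    """
    return itertools.product(*(d.values for d in space.dimensions))


def descriptor_to_str(descriptor: Sequence[str]) -> str:
    return "|".join(descriptor)


def descriptor_from_str(text: str) -> Descriptor:
    return tuple(text.split("|"))


# ---------------------------------------------------------------------------
# CIELAB palette
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabColor:
    """A CIELAB color: lightness L in [0, 100], opponent coordinates a, b."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(f"L={self.L} outside [0, 100]")
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("a/b coordinates must be finite")

    @property
    def chroma(self) -> float:
        return math.hypot(self.a, self.b)

    def distance_to(self, other: "LabColor") -> float:
        return math.sqrt(
            (self.L - other.L) ** 2 + (self.a - other.a) ** 2 + (self.b - other.b) ** 2
        )


def make_color_palette(
    n: int, L: float = 70.0, C: float = 40.0, hue_start_deg: float = 0.0
) -> list[LabColor]:
    """``n`` colors equally spaced in hue on the chroma-``C`` circle at lightness ``L``.

    Adjacent hues differ by 360/n degrees, so all adjacent-pair Euclidean
    Lab distances are equal.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if C <= 0:
        raise ValueError(f"chroma must be > 0, got {C}")
    colors = []
    for i in range(n):
        h = math.radians(hue_start_deg + 360.0 * i / n)
        colors.append(LabColor(L=L, a=C * math.cos(h), b=C * math.sin(h)))
    return colors


def lab_to_srgb(color: LabColor) -> tuple[float, float, float]:
    """Approximate sRGB (D65, components clipped to [0, 1]) for a Lab color."""
    # Lab -> XYZ (D65 white)
    fy = (color.L + 16.0) / 116.0
    fx = fy + color.a / 500.0
    fz = fy - color.b / 200.0

    def f_inv(t: float) -> float:
        d = 6.0 / 29.0
        return t**3 if t > d else 3 * d * d * (t - 4.0 / 29.0)

    xn, yn, zn = 0.95047, 1.0, 1.08883
    x, y, z = xn * f_inv(fx), yn * f_inv(fy), zn * f_inv(fz)
    # XYZ -> linear sRGB
    r = 3.2406 * x - 1.5372 * y - 0.4986 * z
    g = -0.9689 * x + 1.8758 * y + 0.0415 * z
    b = 0.0557 * x - 0.2040 * y + 1.0570 * z

    def gamma(u: float) -> float:
        u = min(max(u, 0.0), 1.0)
        return 12.92 * u if u <= 0.0031308 else 1.055 * u ** (1 / 2.4) - 0.055

    return (gamma(r), gamma(g), gamma(b))


def palette_to_csv(
    colors: Sequence[LabColor],
    stream: IO[str],
    labels: Sequence[str] | None = None,
) -> None:
    """Write a palette as CSV with columns (label, L, a, b, R, G, B)."""
    if labels is not None and len(labels) != len(colors):
        raise ValueError("labels length must match palette length")
    writer = csv.writer(stream)
    writer.writerow(["label", "L", "a", "b", "R", "G", "B"])
    for i, c in enumerate(colors):
        label = labels[i] if labels is not None else f"color_{i}"
        r, g, b = lab_to_srgb(c)
        writer.writerow([label, f"{c.L:.6f}", f"{c.a:.6f}", f"{c.b:.6f}",
                         f"{r:.6f}", f"{g:.6f}", f"{b:.6f}"])


# ---------------------------------------------------------------------------
# Neutral-feature semantics
# ---------------------------------------------------------------------------

def neutral_dimension_count(
    descriptor: Sequence[str], space: FeatureSpace
) -> tuple[int, bool]:
    """Return ``(count, fully_neutral)``: how many dimensions carry the neutral value.

    ``fully_neutral`` is true iff every dimension is neutral — the object
    whose choice aborts a trial.
    """
    desc = space.validate_descriptor(descriptor)
    count = sum(1 for v, d in zip(desc, space.dimensions) if v == d.neutral)
    return count, count == space.n_dimensions


def shared_feature_count(a: Sequence[str], b: Sequence[str]) -> int:
    """Number of dimensions on which two descriptors carry the same value."""
    if len(a) != len(b):
        raise ValueError("descriptors have different lengths")
    return sum(1 for x, y in zip(a, b) if x == y)


# ---------------------------------------------------------------------------
# Constrained sampling
# ---------------------------------------------------------------------------

def sample_target(
    space: FeatureSpace,
    k_nonneutral: int,
    forced_neutral_dims: Iterable[str] = (),
    rng: np.random.Generator | None = None,
) -> Descriptor:
    """Draw a target with exactly ``k_nonneutral`` non-neutral dimensions.

    Dimensions named in ``forced_neutral_dims`` are pinned to their neutral
    value (e.g. forcing the spherical body shape).  The non-neutral
    dimensions are chosen uniformly among the remaining dimensions, and
    each non-neutral value uniformly among that dimension's non-neutral
    values.
    """
    rng = np.random.default_rng() if rng is None else rng
    forced = frozenset(forced_neutral_dims)
    for name in forced:
        space.index(name)  # raises on unknown dimension
    free = [d.name for d in space.dimensions if d.name not in forced]
    if not 0 <= k_nonneutral <= len(free):
        raise FeasibilityError(
            f"k_nonneutral={k_nonneutral} infeasible with "
            f"{len(free)} free dimensions"
        )
    chosen = set(rng.choice(len(free), size=k_nonneutral, replace=False).tolist())
    nonneutral_dims = {free[i] for i in chosen}
    values = []
    for d in space.dimensions:
        if d.name in nonneutral_dims:
            pool = d.non_neutral_values
            if not pool:
                raise FeasibilityError(
                    f"dimension {d.name!r} has no non-neutral values"
                )
            values.append(pool[rng.integers(len(pool))])
        else:
            values.append(d.neutral)
    return tuple(values)


def _count_exact_shared(space: FeatureSpace, target: Descriptor, n_shared: int) -> int:
    """Count descriptors sharing exactly ``n_shared`` values with ``target``,
    excluding the fully neutral object (the target itself shares all values,
    so it is never in this set for n_shared < n_dimensions)."""
    n = space.n_dimensions
    total = 0
    for matching in itertools.combinations(range(n), n_shared):
        prod = 1
        for i, d in enumerate(space.dimensions):
            if i not in matching:
                prod *= d.cardinality - 1
        total += prod
    neutral = space.neutral_descriptor
    if shared_feature_count(neutral, target) == n_shared:
        total -= 1
    return total


def sample_search_array(
    space: FeatureSpace,
    target: Sequence[str],
    n_distractors: int,
    n_shared: int,
    rng: np.random.Generator | None = None,
) -> list[Descriptor]:
    """Sample mutually distinct distractors, each sharing exactly ``n_shared``
    feature values with ``target``.

    No distractor equals the target and none is fully neutral.  Shared
    features are counted as exact per-dimension value matches.
    """
    rng = np.random.default_rng() if rng is None else rng
    target = space.validate_descriptor(target)
    n = space.n_dimensions
    if not 1 <= n_shared <= n - 1:
        raise FeasibilityError(
            f"n_shared must be in [1, {n - 1}]; n_shared={n_shared} would "
            "duplicate the target or share nothing"
        )
    if n_distractors < 0:
        raise ValueError("n_distractors must be >= 0")
    feasible = _count_exact_shared(space, target, n_shared)
    if n_distractors > feasible:
        raise FeasibilityError(
            f"requested {n_distractors} distinct distractors but only "
            f"{feasible} descriptors satisfy the constraint"
        )
    neutral = space.neutral_descriptor
    out: list[Descriptor] = []
    seen: set[Descriptor] = set()
    max_tries = 200 * max(n_distractors, 1)
    tries = 0
    while len(out) < n_distractors and tries < max_tries:
        tries += 1
        matching = set(rng.choice(n, size=n_shared, replace=False).tolist())
        values = []
        for i, d in enumerate(space.dimensions):
            if i in matching:
                values.append(target[i])
            else:
                pool = [v for v in d.values if v != target[i]]
                values.append(pool[rng.integers(len(pool))])
        cand = tuple(values)
        if cand == target or cand == neutral or cand in seen:
            continue
        seen.add(cand)
        out.append(cand)
    if len(out) < n_distractors:
        # rejection stalled (tight constraint): fall back to exhaustive draw
        pool = [
            obj
            for obj in enumerate_objects(space)
            if shared_feature_count(obj, target) == n_shared
            and obj != neutral
            and obj not in seen
        ]
        idx = rng.choice(len(pool), size=n_distractors - len(out), replace=False)
        out.extend(pool[i] for i in idx)
    return out


def sample_learning_array(
    space: FeatureSpace,
    rewarded_dim: str,
    rewarded_value: str,
    n_objects: int,
    varied_dims: Iterable[str],
    rng: np.random.Generator | None = None,
) -> list[Descriptor]:
    """Sample an array for the feature-reward learning task.

    Exactly one object carries ``rewarded_value`` in ``rewarded_dim``.
    Within each varied dimension the objects take distinct non-neutral
    values; all non-varied dimensions are neutral.
    """
    rng = np.random.default_rng() if rng is None else rng
    varied = list(dict.fromkeys(varied_dims))  # preserve order, dedupe
    if rewarded_dim not in varied:
        raise FeasibilityError("rewarded_dim must be one of the varied dimensions")
    rdim = space.dimension(rewarded_dim)
    if rewarded_value == rdim.neutral:
        raise FeasibilityError("rewarded value must not be the neutral value")
    if rewarded_value not in rdim.values:
        raise FeatureSpaceError(
            f"{rewarded_value!r} is not a value of dimension {rewarded_dim!r}"
        )
    if n_objects < 1:
        raise ValueError("n_objects must be >= 1")
    for name in varied:
        d = space.dimension(name)
        if n_objects > len(d.non_neutral_values):
            raise FeasibilityError(
                f"dimension {name!r} has only {len(d.non_neutral_values)} "
                f"non-neutral values; cannot vary {n_objects} objects"
            )

    # per varied dimension: a shuffled assignment of distinct non-neutral values
    assignments: dict[str, list[str]] = {}
    for name in varied:
        d = space.dimension(name)
        if name == rewarded_dim:
            others = [v for v in d.non_neutral_values if v != rewarded_value]
            pick = rng.choice(len(others), size=n_objects - 1, replace=False)
            vals = [rewarded_value] + [others[i] for i in pick]
        else:
            pick = rng.choice(
                len(d.non_neutral_values), size=n_objects, replace=False
            )
            vals = [d.non_neutral_values[i] for i in pick]
        rng.shuffle(vals)
        assignments[name] = vals

    objects = []
    for j in range(n_objects):
        values = []
        for d in space.dimensions:
            if d.name in assignments:
                values.append(assignments[d.name][j])
            else:
                values.append(d.neutral)
        objects.append(tuple(values))
    return objects


# ---------------------------------------------------------------------------
# Definition files
# ---------------------------------------------------------------------------

def load_feature_space(path: str) -> FeatureSpace:
    """Load a feature space from a YAML definition file.

    Schema::

        dimensions:
          - name: <label>
            values: [<label>, ...]
            neutral: <label>
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "dimensions" not in doc:
        raise FeatureSpaceError(f"{path}: expected a mapping with a 'dimensions' key")
    return build_feature_space(doc["dimensions"])


def save_feature_space(space: FeatureSpace, path: str) -> None:
    doc = {
        "dimensions": [
            {"name": d.name, "values": list(d.values), "neutral": d.neutral}
            for d in space.dimensions
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
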