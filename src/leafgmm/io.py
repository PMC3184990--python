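"""Reading and writing landmark data: TPS and NTS ASCII files, outline
polylines, wireframe link lists, and classifier extraction from specimen
labels.

The TPS dialect accepted here is the one produced by the TPS software
series: ``LM=k`` record headers followed by ``k`` coordinate lines, with
optional ``IMAGE=``, ``ID=``, ``SCALE=`` and ``CURVES=``/``POINTS=``
blocks.  Curve blocks are parsed and discarded — outlines used for
visualization come from the dedicated outline file.  The NTS dialect is
the NTSYSpc rectangular matrix layout: one header line, an optional row
label block, and one row of ``x1 y1 x2 y2 ...`` per specimen.

Coordinates are real-valued and y-up; landmark indices are 1-based in
all user-facing interfaces (wireframe links, baselines).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np


class LandmarkParseError(ValueError):
    """A TPS/NTS/outline file could not be parsed; names record and line."""


@dataclass
class LandmarkConfiguration:
    """A single specimen's 2D landmark configuration.

    Parameters
    ----------
    label : str
        Specimen identifier; classifier substrings are extracted from it.
    coords : (k, 2) array
        Landmark coordinates in mm (after applying any scale factor).
        Landmark order is semantic: index ``i`` is the same anatomical
        point in every specimen.
    scale_factor : float
        mm per pixel used during digitization (already applied to
        ``coords``); retained for provenance.
    source_image : str, optional
        Image file the landmarks were digitized on.
    """

    label: str
    coords: np.ndarray
    scale_factor: float = 1.0
    source_image: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"coords must be (k, 2), got {self.coords.shape}")
        if self.coords.shape[0] < 3:
            raise ValueError(f"need at least 3 landmarks, got {self.coords.shape[0]}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinate in specimen {self.label!r}")
        if not self.scale_factor > 0:
            raise ValueError(f"scale_factor must be positive, got {self.scale_factor}")

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class SpecimenClassifiers:
    """Nested grouping variables for one specimen.

    Each leaf belongs to exactly one tree and each tree to exactly one
    population; ``replica`` distinguishes repeated digitizations of the
    same leaf.
    """

    population: str
    tree: str
    leaf: str
    replica: int


@dataclass
class LandmarkDataset:
    """A set of landmark configurations with optional classifiers and
    drawing metadata (wireframe links, outline polyline)."""

    configurations: list[LandmarkConfiguration]
    classifiers: list[SpecimenClassifiers] | None = None
    wireframe: list[tuple[int, int]] | None = None  # 1-based landmark pairs
    outline: np.ndarray | None = None  # (m, 2) polyline

    def __post_init__(self) -> None:
        if self.configurations:
            k = self.configurations[0].k
            for c in self.configurations:
                if c.k != k:
                    raise ValueError(
                        f"inconsistent landmark count: {c.label!r} has {c.k}, expected {k}"
                    )
        if self.classifiers is not None and len(self.classifiers) != len(self.configurations):
            raise ValueError("classifier table length must equal configuration count")
        if self.wireframe is not None:
            k = self.k
            for a, b in self.wireframe:
                if not (1 <= a <= k and 1 <= b <= k):
                    raise ValueError(f"wireframe link ({a}, {b}) outside 1..{k}")

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def k(self) -> int:
        if not self.configurations:
            raise ValueError("empty dataset")
        return self.configurations[0].k

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.configurations]

    def coords_array(self) -> np.ndarray:
        """All configurations stacked as an (n, k, 2) array."""
        return np.stack([c.coords for c in self.configurations])

    def with_classifiers(self, ranges: dict[str, tuple[int, int]]) -> "LandmarkDataset":
        """Return a copy whose classifiers are parsed from the labels."""
        return replace(self, classifiers=parse_classifiers(self.labels, ranges))


# ---------------------------------------------------------------------------
# TPS

def read_tps(path: str | Path, default_scale: float | None = None) -> list[LandmarkConfiguration]:
    """Read a TPS file into a list of configurations.

    If a record carries a ``SCALE=`` line its coordinates are multiplied
    by it (pixels -> mm).  If absent, the first record's scale is reused
    — the convention of setting the scale on the first image only — and
    failing that ``default_scale`` (or 1.0).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    records: list[dict] = []
    current: dict | None = None
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        key, _, value = line.partition("=")
        key_u = key.strip().upper()
        if key_u == "LM":
            try:
                k = int(value)
            except ValueError:
                raise LandmarkParseError(f"{path.name}: bad LM header at line {i}: {line!r}")
            current = {"k": k, "points": [], "line": i}
            records.append(current)
        elif current is None:
            raise LandmarkParseError(f"{path.name}: data before first LM= header at line {i}")
        elif key_u == "CURVES":
            # consume and discard curve blocks (POINTS= sub-headers + points)
            try:
                n_curves = int(value)
            except ValueError:
                raise LandmarkParseError(f"{path.name}: bad CURVES count at line {i}")
            for _ in range(n_curves):
                sub = lines[i].strip()
                i += 1
                skey, _, sval = sub.partition("=")
                if skey.strip().upper() != "POINTS":
                    raise LandmarkParseError(f"{path.name}: expected POINTS= at line {i}")
                i += int(sval)
        elif key_u == "IMAGE":
            current["image"] = value.strip()
        elif key_u == "ID":
            current["id"] = value.strip()
        elif key_u == "SCALE":
            try:
                current["scale"] = float(value)
            except ValueError:
                raise LandmarkParseError(f"{path.name}: bad SCALE at line {i}: {line!r}")
        else:
            parts = line.split()
            if len(parts) != 2:
                raise LandmarkParseError(
                    f"{path.name}: expected 'x y' coordinate at line {i}, got {line!r}"
                )
            try:
                current["points"].append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise LandmarkParseError(f"{path.name}: non-numeric coordinate at line {i}")

    configs: list[LandmarkConfiguration] = []
    first_scale: float | None = None
    for idx, rec in enumerate(records):
        if len(rec["points"]) != rec["k"]:
            raise LandmarkParseError(
                f"{path.name}: record {idx + 1} (line {rec['line']}) declares "
                f"LM={rec['k']} but has {len(rec['points'])} points"
            )
        scale = rec.get("scale")
        if scale is not None and first_scale is None:
            first_scale = scale
        if scale is None:
            scale = first_scale if first_scale is not None else (default_scale or 1.0)
        label = rec.get("id") or rec.get("image") or f"specimen_{idx + 1}"
        if label.lower().endswith((".jpg", ".png", ".tif", ".jpeg", ".bmp")):
            label = label.rsplit(".", 1)[0]
        coords = np.array(rec["points"], dtype=float) * scale
        configs.append(
            LandmarkConfiguration(
                label=label, coords=coords, scale_factor=scale, source_image=rec.get("image")
            )
        )
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], path: str | Path, precision: int = 8) -> None:
    """Write configurations to a TPS file re-readable by :func:`read_tps`.

    Coordinates are written in mm with ``SCALE=1``, so reading the file
    back reproduces the coordinates bit-identically at the stated
    precision.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("cannot write an empty configuration list")
    k = configs[0].k
    for c in configs:
        if c.k != k:
            raise ValueError(f"heterogeneous landmark counts: {c.label!r} has {c.k}, expected {k}")
    out: list[str] = []
    for c in configs:
        out.append(f"LM={c.k}")
        for x, y in c.coords:
            out.append(f"{x:.{precision}f} {y:.{precision}f}")
        if c.source_image:
            out.append(f"IMAGE={c.source_image}")
        out.append(f"ID={c.label}")
        out.append("SCALE=1.0")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# NTS

def read_nts(path: str | Path) -> list[LandmarkConfiguration]:
    """Read an NTSYSpc rectangular coordinate matrix.

    Header: ``<type> <nrows>[L] <ncols>[L] <missing> [dim=2]``; an ``L``
    suffix on the row count announces a row-label block before the data.
    Data rows are ``x1 y1 x2 y2 ...``; the column count must be even.
    """
    path = Path(path)
    tokens_lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.lstrip().startswith(('"', "'"))
    ]
    if not tokens_lines:
        raise LandmarkParseError(f"{path.name}: empty file")
    header = tokens_lines[0].split()
    if len(header) < 4:
        raise LandmarkParseError(f"{path.name}: NTS header needs >=4 fields, got {header}")
    row_field, col_field = header[1], header[2]
    has_labels = row_field.upper().endswith("L")
    n_rows = int(row_field.rstrip("Ll"))
    n_cols = int(col_field.rstrip("Ll"))
    if n_cols % 2 != 0:
        raise LandmarkParseError(f"{path.name}: column count {n_cols} is odd; expected 2k")
    k = n_cols // 2

    tokens: list[str] = []
    for ln in tokens_lines[1:]:
        tokens.extend(ln.split())
    labels: list[str]
    if has_labels:
        if len(tokens) < n_rows:
            raise LandmarkParseError(f"{path.name}: label block shorter than row count")
        labels = tokens[:n_rows]
        tokens = tokens[n_rows:]
    else:
        labels = [f"specimen_{i + 1}" for i in range(n_rows)]
    if len(tokens) != n_rows * n_cols:
        raise LandmarkParseError(
            f"{path.name}: expected {n_rows * n_cols} data values "
            f"({n_rows} rows x {n_cols} cols), found {len(tokens)}"
        )
    try:
        data = np.array(tokens, dtype=float).reshape(n_rows, k, 2)
    except ValueError:
        raise LandmarkParseError(f"{path.name}: non-numeric value in data block")
    return [LandmarkConfiguration(label=labels[i], coords=data[i]) for i in range(n_rows)]


def write_nts(
    configs: Sequence[LandmarkConfiguration] | LandmarkDataset,
    path: str | Path,
    precision: int = 8,
) -> None:
    """Write configurations as a labeled NTS matrix (``1 nL 2k 0 dim=2``)."""
    if isinstance(configs, LandmarkDataset):
        configs = configs.configurations
    configs = list(configs)
    if not configs:
        raise ValueError("cannot write an empty configuration list")
    k = configs[0].k
    for c in configs:
        if c.k != k:
            raise ValueError(f"heterogeneous landmark counts: {c.label!r} has {c.k}, expected {k}")
    lines = [f"1 {len(configs)}L {2 * k} 0 dim=2"]
    lines.extend(c.label for c in configs)
    for c in configs:
        lines.append(" ".join(f"{v:.{precision}f}" for v in c.coords.ravel()))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# classifiers

def parse_classifiers(
    labels: Sequence[str],
    ranges: dict[str, tuple[int, int]] | None = None,
) -> list[SpecimenClassifiers]:
    """Extract nested classifiers from specimen labels by character range.

    ``ranges`` maps each of ``population``, ``tree``, ``leaf``,
    ``replica`` to a 1-based inclusive character range, the convention
    used when labels follow the ``Busso_T01_L1_R1`` pattern (population
    chars 1-5, tree 1-9, leaf 1-12, replica 14).  Those positions are
    the default.  Nesting consistency (leaf -> tree -> population) is
    validated and violations raise ``ValueError``.
    """
    if ranges is None:
        ranges = {"population": (1, 5), "tree": (1, 9), "leaf": (1, 12), "replica": (15, 15)}
    for key in ("population", "tree", "leaf", "replica"):
        if key not in ranges:
            raise ValueError(f"missing classifier range {key!r}")
    widest = max(hi for _, hi in ranges.values())

    def cut(label: str, rng: tuple[int, int]) -> str:
        lo, hi = rng
        return label[lo - 1 : hi]

    out: list[SpecimenClassifiers] = []
    for label in labels:
        if len(label) < widest:
            raise ValueError(
                f"label {label!r} shorter than the widest classifier range (needs {widest} chars)"
            )
        rep_str = cut(label, ranges["replica"])
        try:
            replica = int(rep_str)
        except ValueError:
            raise ValueError(f"label {label!r}: replica field {rep_str!r} is not an integer")
        out.append(
            SpecimenClassifiers(
                population=cut(label, ranges["population"]),
                tree=cut(label, ranges["tree"]),
                leaf=cut(label, ranges["leaf"]),
                replica=replica,
            )
        )

    # nesting consistency: each leaf under one tree, each tree under one population
    tree_of_leaf: dict[str, str] = {}
    pop_of_tree: dict[str, str] = {}
    for c in out:
        if tree_of_leaf.setdefault(c.leaf, c.tree) != c.tree:
            raise ValueError(f"leaf {c.leaf!r} appears under two trees")
        if pop_of_tree.setdefault(c.tree, c.population) != c.population:
            raise ValueError(f"tree {c.tree!r} appears under two populations")
    return out


# ---------------------------------------------------------------------------
# outline

def read_outline(path: str | Path) -> np.ndarray:
    """Read a two-column ASCII outline polyline.

    A single leading number alone on the first line is tolerated and
    skipped (some exporters prepend a vertex count).  At least 3 points
    are required.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    start = 0
    if lines and len(lines[0].split()) == 1:
        start = 1  # leading count line
    for i, ln in enumerate(lines[start:], start=start + 1):
        parts = ln.split()
        if len(parts) != 2:
            raise LandmarkParseError(f"{path.name}: expected two columns at line {i}, got {ln!r}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise LandmarkParseError(f"{path.name}: non-numeric outline value at line {i}")
    if len(rows) < 3:
        raise LandmarkParseError(f"{path.name}: outline needs at least 3 points, got {len(rows)}")
    return np.array(rows, dtype=float)


def write_outline(outline: np.ndarray, path: str | Path, precision: int = 8) -> None:
    outline = np.asarray(outline, dtype=float)
    lines = [f"{x:.{precision}f} {y:.{precision}f}" for x, y in outline]
    Path(path).write_text("\n".join(lines) + "\n")
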