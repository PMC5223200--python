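"""Domain types, lectin panel registry, and spot-table / manifest IO.

The spot-table dialect is a minimal tab-delimited subset of the GenePix
Results (GPR) format: a header row with the columns ``Slide``, ``Block``,
``Row``, ``Column``, ``Name``, ``F532 Median``, ``B532 Median``, ``Flags``.
Leading GPR-style metadata lines (``ATF 1.0``, dimension counts, quoted
``"key=value"`` pairs) are skipped tolerantly.  Full multi-wavelength GPR
files and other scanner dialects are out of scope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

from glycolect.errors import (
    DuplicateSpotError,
    ManifestError,
    PanelMismatchError,
    SpotTableFormatError,
)

__all__ = [
    "LectinAnnotation",
    "Panel",
    "SpotRecord",
    "GroupManifest",
    "default_panel",
    "read_panel_file",
    "write_panel_file",
    "read_spot_table",
    "write_spot_table",
    "read_manifest",
    "SPOT_TABLE_COLUMNS",
]

SPOT_TABLE_COLUMNS = (
    "Slide",
    "Block",
    "Row",
    "Column",
    "Name",
    "F532 Median",
    "B532 Median",
    "Flags",
)


@dataclass(frozen=True)
class LectinAnnotation:
    """One panel entry: a lectin and its glycan-specificity string."""

    name: str
    specificity: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("lectin name must be nonempty")


@dataclass(frozen=True)
class Panel:
    """An ordered lectin panel plus the slide replicate geometry.

    Default geometry is 3 replicate spots per lectin per block and 3 blocks
    per slide.
    """

    lectins: tuple[LectinAnnotation, ...]
    spots_per_lectin_per_block: int = 3
    blocks_per_slide: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "lectins", tuple(self.lectins))
        if len(self.lectins) == 0:
            raise ValueError("panel must contain at least one lectin")
        names = [lec.name for lec in self.lectins]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate lectin names in panel: {dupes}")
        if self.spots_per_lectin_per_block < 1 or self.blocks_per_slide < 1:
            raise ValueError("layout counts must be >= 1")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(lec.name for lec in self.lectins)

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.lectins)

    def get(self, name: str) -> LectinAnnotation:
        for lec in self.lectins:
            if lec.name == name:
                return lec
        raise KeyError(name)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class SpotRecord:
    """One spot's raw quantification (1-based GPR-style coordinates)."""

    slide_id: str
    block: int
    row: int
    column: int
    lectin: str
    fg_median: float
    bg_median: float
    flag: int = 0

    def __post_init__(self) -> None:
        if self.block < 1 or self.row < 1 or self.column < 1:
            raise ValueError("block/row/column indices are 1-based and must be >= 1")
        for label, value in (("fg_median", self.fg_median), ("bg_median", self.bg_median)):
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{label} must be finite and non-negative, got {value!r}")

    @property
    def is_flagged(self) -> bool:
        """GPR convention: negative flags mark bad spots."""
        return self.flag < 0


@dataclass(frozen=True)
class GroupManifest:
    """Maps an experimental group to its slides and its model/control role."""

    group_id: str
    slide_ids: tuple[str, ...]
    role: str = "model"

    def __post_init__(self) -> None:
        object.__setattr__(self, "slide_ids", tuple(self.slide_ids))
        if not self.group_id:
            raise ManifestError("group_id must be nonempty")
        if len(self.slide_ids) == 0:
            raise ManifestError(f"group {self.group_id!r} has no slides")
        if self.role not in ("model", "control"):
            raise ManifestError(
                f"group {self.group_id!r}: role must be 'model' or 'control', got {self.role!r}"
            )


# ---------------------------------------------------------------------------
# Built-in 37-lectin registry.
#
# The first 23 entries carry the specificity strings of the study panel's
# published members; the remaining 14 slots are registry placeholders with
# commonly cited specificities (the full printed layout of the original
# slide is not public).  Placeholders are marked via ``source`` and the
# whole panel can be replaced from a user TSV with ``read_panel_file``.
# ---------------------------------------------------------------------------

_PLACEHOLDER = "registry placeholder (common specificity; override with a panel file)"

_REGISTRY: tuple[tuple[str, str, str], ...] = (
    ("PSA", "Fucα-1,6GlcNAc, α-D-Man, α-D-Glc", ""),
    ("WFA", "terminating in GalNAcα/β1-3/6 Gal", ""),
    ("PTL-I", "GalNAc, GalNAcα-1,3 Gal, GalNAcα-1,3Galβ-1,3/4Glc", ""),
    ("AAL", "Fucα1-6 GlcNAc(core fucose), Fucα1-3(Galβ1-4)GlcNAc", ""),
    ("PTL-II", "Gal, blood group H, T-antigen", ""),
    ("SBA", "α- or β-linked terminal GalNAc, (GalNAc)n, GalNAcα1-3 Gal", ""),
    ("UEA-I", "Fucα1-2Galβ1-4Glc(NAc)", ""),
    (
        "PHA-E + L",
        "Bisecting GlcNAc, bi-antennary N-glycans, tri- and tetra-antennary complex-type N-glycan",
        "",
    ),
    ("SNA", "Sia2-6Gal/GalNAc", ""),
    ("ECA", "Galβ-1,4GlcNAc (type II), Galβ1-3GlcNAc (type I)", ""),
    ("LCA", "α-D-Man, Fucα-1,6GlcNAc, α-D-Glc", ""),
    ("VVA", "terminal GalNAc, GalNAcα-Ser/Thr(Tn), GalNAcα1-3 Gal", ""),
    ("GNA", "High-Mannose, Manα1-3Man", ""),
    ("DBA", "αGalNAc, Tn antigen, GalNAcα1-3((Fucα1-2))Gal (blood group A antigen)", ""),
    ("NPA", "High-Mannose, Manα1-6Man", ""),
    ("SJA", "Terminal in GalNAc and Gal", ""),
    ("GLS-I", "αGalNAc, αGal, anti-A and B", ""),
    (
        "STL",
        "trimers and tetramers of GlcNAc, core (GlcNAc) of N-glycan, "
        "oligosaccharidecontaining GlcNAc and MurNAc",
        "",
    ),
    ("ConA", "High-Mannose, Manα1-6(Manα1-3)Man, αMannose, αGlc", ""),
    ("BPL", "Galβ1-3GalNAc, Terminal GalNAc", ""),
    ("PHA-E", "Bisecting GlcNAc, biantennary complex-type N-glycan with outer Gal", ""),
    ("LEL", "(GlcNAc)n, high mannose-type N-glycans", ""),
    ("WGA", "(GlcNAc)n, GlcNAcβ1-4MurNAc, multivalent Sia", ""),
    # -- placeholders below ------------------------------------------------
    ("MAL-I", "Siaα2-3Galβ1-4GlcNAc", _PLACEHOLDER),
    ("MAL-II", "Siaα2-3Galβ1-3GalNAc", _PLACEHOLDER),
    ("PNA", "Galβ1-3GalNAc (T antigen)", _PLACEHOLDER),
    ("RCA120", "β-D-Gal, Galβ1-4GlcNAc", _PLACEHOLDER),
    ("Jacalin", "Galβ1-3GalNAcα-Ser/Thr (T antigen), GalNAcα-Ser/Thr (Tn)", _PLACEHOLDER),
    ("DSA", "(GlcNAc)n, Galβ1-4GlcNAc", _PLACEHOLDER),
    ("GSL-II", "terminal GlcNAc, agalactosylated tri/tetra-antennary N-glycans", _PLACEHOLDER),
    ("HHL", "High-Mannose, Manα1-3Man, Manα1-6Man", _PLACEHOLDER),
    ("EEL", "Galα1-3Gal (blood group B)", _PLACEHOLDER),
    ("MPL", "Galβ1-3GalNAc, Tn antigen", _PLACEHOLDER),
    ("ACA", "Galβ1-3GalNAcα-Ser/Thr (T antigen)", _PLACEHOLDER),
    ("LTL", "Fucα1-3GlcNAc, Lewis x", _PLACEHOLDER),
    ("PWM", "branched (GlcNAc)n", _PLACEHOLDER),
    ("LPA", "Sia, N-glycolylneuraminic acid", _PLACEHOLDER),
)


def default_panel() -> Panel:
    """Return the built-in 37-lectin panel with the default 3x3 layout.

    Deterministic and order-stable across calls.
    """
    return Panel(tuple(LectinAnnotation(n, s, src) for n, s, src in _REGISTRY))


# ---------------------------------------------------------------------------
# Panel file IO (TSV: Name <tab> Specificity)
# ---------------------------------------------------------------------------

def read_panel_file(path: Union[str, Path], *, spots_per_lectin_per_block: int = 3,
                    blocks_per_slide: int = 3) -> Panel:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise SpotTableFormatError(f"{path}: empty panel file")
    header = [h.strip() for h in lines[0].split("\t")]
    for col in ("Name", "Specificity"):
        if col not in header:
            raise SpotTableFormatError(f"{path}: panel file missing column {col!r}")
    iname, ispec = header.index("Name"), header.index("Specificity")
    lectins = []
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        lectins.append(LectinAnnotation(parts[iname].strip(), parts[ispec].strip(), "user panel"))
    return Panel(tuple(lectins), spots_per_lectin_per_block, blocks_per_slide)


def write_panel_file(panel: Panel, path: Union[str, Path]) -> Path:
    path = Path(path)
    rows = ["Name\tSpecificity"]
    rows += [f"{lec.name}\t{lec.specificity}" for lec in panel.lectins]
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Spot table IO
# ---------------------------------------------------------------------------

def _is_metadata_line(line: str) -> bool:
    stripped = line.strip()
    if not stripped:
        return True
    if stripped.startswith('"') and "=" in stripped:
        return True
    if stripped.upper().startswith("ATF"):
        return True
    parts = stripped.split("\t")
    if all(p.strip().lstrip("-").isdigit() for p in parts):
        return True
    return False


def read_spot_table(path: Union[str, Path], panel: Panel) -> list[SpotRecord]:
    """Parse a spot table, validating lectin names against ``panel``.

    Raises :class:`SpotTableFormatError` when a required column is absent,
    :class:`PanelMismatchError` listing any unknown lectin names, and
    :class:`DuplicateSpotError` when two rows share the same address.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text(encoding="utf-8").splitlines()

    header_idx = None
    for i, line in enumerate(lines):
        if _is_metadata_line(line):
            continue
        header_idx = i
        break
    if header_idx is None:
        raise SpotTableFormatError(f"{path}: no header row found")

    header = [h.strip().strip('"') for h in lines[header_idx].split("\t")]
    for col in SPOT_TABLE_COLUMNS:
        if col not in header:
            raise SpotTableFormatError(f"{path}: missing required column {col!r}")
    idx = {col: header.index(col) for col in SPOT_TABLE_COLUMNS}

    records: list[SpotRecord] = []
    unknown: set[str] = set()
    seen: set[tuple] = set()
    for lineno, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < len(header):
            raise SpotTableFormatError(f"{path}:{lineno}: expected {len(header)} fields")
        try:
            rec = SpotRecord(
                slide_id=parts[idx["Slide"]].strip().strip('"'),
                block=int(parts[idx["Block"]]),
                row=int(parts[idx["Row"]]),
                column=int(parts[idx["Column"]]),
                lectin=parts[idx["Name"]].strip().strip('"'),
                fg_median=float(parts[idx["F532 Median"]]),
                bg_median=float(parts[idx["B532 Median"]]),
                flag=int(parts[idx["Flags"]]),
            )
        except (ValueError, IndexError) as exc:
            raise SpotTableFormatError(f"{path}:{lineno}: {exc}") from exc
        if rec.lectin not in panel:
            unknown.add(rec.lectin)
        key = (rec.slide_id, rec.block, rec.lectin, rec.row, rec.column)
        if key in seen:
            raise DuplicateSpotError(f"{path}:{lineno}: duplicate spot address {key}")
        seen.add(key)
        records.append(rec)

    if unknown:
        raise PanelMismatchError(
            f"{path}: lectins not in panel: {', '.join(sorted(unknown))}"
        )
    return records


def write_spot_table(records: Sequence[SpotRecord], path: Union[str, Path]) -> Path:
    """Write records in the dialect read by :func:`read_spot_table`.

    Floats are written with ``repr`` so that ``read(write(x)) == x``
    field-for-field.
    """
    if not records:
        raise ValueError("cannot write an empty spot table")
    path = Path(path)
    out = ["\t".join(SPOT_TABLE_COLUMNS)]
    for rec in records:
        out.append(
            "\t".join(
                (
                    rec.slide_id,
                    str(rec.block),
                    str(rec.row),
                    str(rec.column),
                    rec.lectin,
                    repr(rec.fg_median),
                    repr(rec.bg_median),
                    str(rec.flag),
                )
            )
        )
    path.write_text("\n".join(out) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Manifest IO (JSON mapping or TSV rows)
# ---------------------------------------------------------------------------

def read_manifest(path: Union[str, Path]) -> list[GroupManifest]:
    """Read a group manifest.

    JSON form: ``{"SAD": {"role": "model", "slides": ["s1", ...]}, ...}``.
    TSV form: header ``Group  Slide  Role`` with one row per slide.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ManifestError(f"{path}: invalid JSON manifest: {exc}") from exc
        if not isinstance(payload, Mapping):
            raise ManifestError(f"{path}: JSON manifest must be an object")
        groups = []
        for gid, entry in payload.items():
            if not isinstance(entry, Mapping) or "slides" not in entry:
                raise ManifestError(f"{path}: group {gid!r} must map to {{'slides': [...], 'role': ...}}")
            groups.append(GroupManifest(gid, tuple(entry["slides"]), entry.get("role", "model")))
        return groups

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ManifestError(f"{path}: empty manifest")
    header = [h.strip() for h in lines[0].split("\t")]
    for col in ("Group", "Slide", "Role"):
        if col not in header:
            raise ManifestError(f"{path}: manifest missing column {col!r}")
    ig, is_, ir = header.index("Group"), header.index("Slide"), header.index("Role")
    slides: dict[str, list[str]] = {}
    roles: dict[str, str] = {}
    for line in lines[1:]:
        parts = line.split("\t")
        gid, slide, role = parts[ig].strip(), parts[is_].strip(), parts[ir].strip()
        slides.setdefault(gid, []).append(slide)
        if gid in roles and roles[gid] != role:
            raise ManifestError(f"{path}: conflicting roles for group {gid!r}")
        roles[gid] = role
    return [GroupManifest(gid, tuple(sl), roles[gid]) for gid, sl in slides.items()]
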