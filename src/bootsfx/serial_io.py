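"""Readers and writers: stream chunks, reflection tables, density maps, config.

The stream dialect is a minimal subset of the CrystFEL stream reflection
block, with chunks delimited by ``----- Begin chunk -----`` /
``----- End chunk -----`` and reflection rows between
``Reflections measured after indexing`` and ``End of reflections``.
Only the first five columns (h, k, l, I, sigma) are consumed; extra columns
(peak, background, panel coordinates) are ignored, so real CrystFEL chunks
parse.  Parsers never silently drop entities: counts of parsed and skipped
lines are recorded on the returned objects.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import yaml

from .crystal import UnitCell
from .framesim import Frame, FrameSet
from .maps import DensityMap
from .reflections import ReflectionSet

__all__ = [
    "read_stream",
    "write_stream",
    "read_reflections",
    "write_reflections",
    "read_map",
    "write_map",
    "load_config",
    "RunManifest",
]

logger = logging.getLogger("bootsfx")

BEGIN_CHUNK = "----- Begin chunk -----"
END_CHUNK = "----- End chunk -----"
BEGIN_REFL = "Reflections measured after indexing"
END_REFL = "End of reflections"


def write_stream(frames: FrameSet, path) -> None:
    """Write frames as stream chunks, ordered by frame_id then hkl."""
    lines: list[str] = ["# bootsfx stream 1.0"]
    for fr in sorted(frames.frames, key=lambda f: f.frame_id):
        lines.append(BEGIN_CHUNK)
        lines.append(f"Image serial number: {fr.frame_id}")
        lines.append(BEGIN_REFL)
        lines.append("   h    k    l           I       sigma(I)")
        order = np.lexsort((fr.hkl[:, 2], fr.hkl[:, 1], fr.hkl[:, 0]))
        for i in order:
            h, k, l = fr.hkl[i]
            lines.append(
                f"{h:4d} {k:4d} {l:4d} {fr.i_partial[i]:.17g} {fr.sigma[i]:.17g}"
            )
        lines.append(END_REFL)
        lines.append(END_CHUNK)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_stream(path) -> FrameSet:
    """Parse stream chunks into a FrameSet.

    Unknown header lines are ignored (a count is logged and recorded in the
    returned set's params); columns beyond the first five are dropped.
    Unterminated chunks and non-numeric rows raise with the line number.
    """
    text = Path(path).read_text(encoding="utf-8")
    frames: list[Frame] = []
    in_chunk = False
    in_refl = False
    chunk_start = 0
    serial: int | None = None
    rows: list[tuple[int, int, int, float, float]] = []
    n_skipped_headers = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line == BEGIN_CHUNK:
            if in_chunk:
                raise ValueError(f"line {chunk_start}: unterminated chunk")
            in_chunk, in_refl = True, False
            chunk_start = lineno
            serial = None
            rows = []
            continue
        if line == END_CHUNK:
            if not in_chunk:
                raise ValueError(f"line {lineno}: end marker outside a chunk")
            if in_refl:
                raise ValueError(f"line {lineno}: unterminated reflection block")
            fid = serial if serial is not None else len(frames)
            arr = np.array(rows, dtype=float).reshape(-1, 5)
            frames.append(
                Frame(
                    frame_id=fid,
                    hkl=arr[:, :3].astype(int),
                    i_partial=arr[:, 3],
                    sigma=arr[:, 4],
                )
            )
            in_chunk = False
            continue
        if not in_chunk:
            continue
        if line == BEGIN_REFL:
            in_refl = True
            continue
        if line == END_REFL:
            in_refl = False
            continue
        if in_refl:
            tokens = line.split()
            if tokens and tokens[0] in ("h",):
                continue  # column header row
            if len(tokens) < 5:
                raise ValueError(f"line {lineno}: expected >= 5 columns")
            try:
                h, k, l = (int(tokens[i]) for i in range(3))
                i_val, sig = float(tokens[3]), float(tokens[4])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric reflection row") from exc
            rows.append((h, k, l, i_val, sig))
        else:
            if line.startswith("Image serial number:"):
                serial = int(line.split(":", 1)[1])
            else:
                n_skipped_headers += 1
    if in_chunk:
        raise ValueError(f"line {chunk_start}: unterminated chunk")
    if n_skipped_headers:
        logger.info("read_stream: ignored %d unknown header lines", n_skipped_headers)
    # renumber to dense ids but keep original serials in params
    serials = [f.frame_id for f in frames]
    for i, fr in enumerate(frames):
        fr.frame_id = i
    return FrameSet(
        frames=frames,
        truth_label=str(path),
        params={
            "n_chunks": len(frames),
            "n_skipped_header_lines": n_skipped_headers,
            "original_serials": serials,
        },
    )


# ---------------------------------------------------------------------------
# Reflection tables
# ---------------------------------------------------------------------------

def write_reflections(refls: ReflectionSet, path) -> None:
    """Columnar text table ``h k l F [phase] [sigF]`` (phase in degrees)."""
    cols = ["h", "k", "l", "F"]
    if refls.has_phases:
        cols.append("phase")
    if refls.sigma is not None:
        cols.append("sigF")
    lines = [" ".join(cols)]
    for i in range(len(refls)):
        parts = [
            str(refls.hkl[i, 0]),
            str(refls.hkl[i, 1]),
            str(refls.hkl[i, 2]),
            f"{refls.amplitude[i]:.17g}",
        ]
        if refls.has_phases:
            parts.append(f"{np.degrees(refls.phase[i]):.17g}")
        if refls.sigma is not None:
            parts.append(f"{refls.sigma[i]:.17g}")
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_reflections(path, cell: UnitCell | None = None, d_min: float | None = None,
                     role: str = "calculated") -> ReflectionSet:
    """Read the columnar reflection table; missing sigF/phase columns are
    flagged by their absence on the returned set."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty reflection table")
    header = lines[0].split()
    known = {"h", "k", "l", "F", "phase", "sigF"}
    if header[:4] != ["h", "k", "l", "F"] or not set(header) <= known:
        raise ValueError(f"{path}: unknown header {header}")
    idx = {name: i for i, name in enumerate(header)}
    data = [ln.split() for ln in lines[1:] if ln.strip()]
    arr = np.array(data, dtype=float)
    if arr.size and arr.shape[1] != len(header):
        raise ValueError(f"{path}: column count does not match header")
    hkl = arr[:, :3].astype(int) if arr.size else np.zeros((0, 3), int)
    seen = set()
    for row in hkl:
        t = tuple(row)
        if t in seen:
            raise ValueError(f"{path}: duplicate hkl {t}")
        seen.add(t)
    amp = arr[:, idx["F"]] if arr.size else np.zeros(0)
    phase = np.radians(arr[:, idx["phase"]]) if "phase" in idx and arr.size else None
    sigma = arr[:, idx["sigF"]] if "sigF" in idx and arr.size else None
    return ReflectionSet(
        hkl=hkl, amplitude=amp, phase=phase, sigma=sigma,
        cell=cell, d_min=d_min, role=role,
    )


# ---------------------------------------------------------------------------
# Density maps: CCP4/MRC (gemmi) or a portable text grid
# ---------------------------------------------------------------------------

def write_map(dmap: DensityMap, path) -> None:
    """Write a density map.

    ``.ccp4``/``.mrc``/``.map`` go through gemmi as mode-2 CCP4 maps; any
    other extension writes the portable text grid (lossless to ~1e-7
    relative either way).
    """
    path = Path(path)
    if path.suffix.lower() in (".ccp4", ".mrc", ".map"):
        grid = gemmi.FloatGrid(*dmap.shape)
        grid.set_unit_cell(dmap.cell._gemmi)
        grid.spacegroup = gemmi.SpaceGroup("P1")
        np.asarray(grid, dtype=np.float32)[:] = dmap.values.astype(np.float32)
        ccp4 = gemmi.Ccp4Map()
        ccp4.grid = grid
        ccp4.update_ccp4_header()
        ccp4.write_ccp4_map(str(path))
        return
    c = dmap.cell
    lines = [
        "# bootsfx density grid 1.0",
        f"cell: {c.a:.17g} {c.b:.17g} {c.c:.17g} {c.alpha:.17g} {c.beta:.17g} {c.gamma:.17g}",
        "shape: {} {} {}".format(*dmap.shape),
    ]
    lines.extend(f"{v:.9g}" for v in dmap.values.ravel())
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_map(path) -> DensityMap:
    path = Path(path)
    if path.suffix.lower() in (".ccp4", ".mrc", ".map"):
        ccp4 = gemmi.read_ccp4_map(str(path))
        g = ccp4.grid
        cell = UnitCell(g.unit_cell.a, g.unit_cell.b, g.unit_cell.c,
                        g.unit_cell.alpha, g.unit_cell.beta, g.unit_cell.gamma)
        return DensityMap(values=np.array(g, dtype=float), cell=cell, label=str(path))
    lines = path.read_text(encoding="utf-8").splitlines()
    cell_line = shape = None
    values: list[float] = []
    for ln in lines:
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        if ln.startswith("cell:"):
            cell_line = [float(x) for x in ln.split(":", 1)[1].split()]
        elif ln.startswith("shape:"):
            shape = tuple(int(x) for x in ln.split(":", 1)[1].split())
        else:
            values.append(float(ln))
    if cell_line is None or shape is None:
        raise ValueError(f"{path}: missing cell or shape header")
    cell = UnitCell(*cell_line)
    arr = np.array(values).reshape(shape)
    return DensityMap(values=arr, cell=cell, label=str(path))


# ---------------------------------------------------------------------------
# Config and run manifests
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """YAML (or JSON, a YAML subset) config file -> dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


@dataclass
class RunManifest:
    """Machine-readable record of one CLI run."""

    command: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    version: str = "0.1.0"
    timestamp: str = ""

    def write(self, path) -> None:
        data = asdict(self)
        if not data["timestamp"]:
            data["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        Path(path).write_text(json.dumps(data, indent=2, default=str) + "\n",
                              encoding="utf-8")

    @classmethod
    def read(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**data)
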