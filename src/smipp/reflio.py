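"""Reflection file formats, ground-truth sidecars and configuration files.

The native format is a whitespace text file:

    # cell 13.0 13.5 12.6 90.0 90.0 90.0
    # d_min 1.00
    # n_reflections 4640
    h k l E [phase_deg]

Indices must be Friedel-unique; the optional phase column appears only in
ground-truth sidecars, never in engine input.  An adapter converts deposited
MTZ or structure-factor mmCIF files to this format.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import gemmi
import numpy as np
import yaml

from .cell import UnitCell
from .engine import PhasingConfig
from .reflections import ReflectionSet


def write_reflections(refl: ReflectionSet, path, phases=None) -> None:
    """Write the native text format; phases (radians) go out in degrees."""
    lines = [
        f"# cell {refl.cell.a:.4f} {refl.cell.b:.4f} {refl.cell.c:.4f} "
        f"{refl.cell.alpha:.3f} {refl.cell.beta:.3f} {refl.cell.gamma:.3f}",
        f"# d_min {refl.d_min:.4f}",
        f"# n_reflections {len(refl)}",
    ]
    for i, (hkl, e) in enumerate(zip(refl.indices, refl.E)):
        row = f"{hkl[0]} {hkl[1]} {hkl[2]} {e:.6f}"
        if phases is not None:
            row += f" {np.degrees(phases[i]):.4f}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def read_reflections(path, with_phases: bool = False):
    """Parse the native format into a ReflectionSet (and phases if asked).

    Malformed lines are reported with their line number; duplicate or
    Friedel-mate duplicate indices are rejected by the container.
    """
    cell = None
    d_min = None
    indices, E, phases = [], [], []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts and parts[0] == "cell":
                cell = UnitCell(*(float(v) for v in parts[1:7]))
            elif parts and parts[0] == "d_min":
                d_min = float(parts[1])
            continue
        parts = line.split()
        if len(parts) not in (4, 5):
            raise ValueError(f"{path}:{lineno}: expected 'h k l E [phase]', "
                             f"got {len(parts)} fields")
        try:
            h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
            e = float(parts[3])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        indices.append((h, k, l))
        E.append(e)
        if len(parts) == 5:
            phases.append(np.radians(float(parts[4])))
    if cell is None or d_min is None:
        raise ValueError(f"{path}: missing '# cell' or '# d_min' header")
    refl = ReflectionSet(cell, np.array(indices), np.array(E), d_min)
    if with_phases:
        if len(phases) != len(E):
            raise ValueError(f"{path}: phase column incomplete")
        return refl, np.mod(np.array(phases), 2.0 * np.pi)
    return refl


def write_ground_truth(gt, refl: ReflectionSet, path) -> None:
    """Sidecar with true phases and the generating sites (validation only)."""
    lines = [
        f"# n_engine {gt.n_engine}",
        f"# n_atoms {gt.structure.n_atoms}",
    ]
    for s in gt.structure.sites:
        lines.append(f"# site {s.x:.6f} {s.y:.6f} {s.z:.6f} {s.w:.1f} {s.label}")
    Path(path).write_text("\n".join(lines) + "\n")
    with open(path, "a") as fh:
        for hkl, ph in zip(refl.indices, gt.true_phases):
            fh.write(f"{hkl[0]} {hkl[1]} {hkl[2]} {np.degrees(ph):.4f}\n")


def read_ground_truth(path, refl: ReflectionSet):
    """Load a sidecar; returns a GroundTruth aligned to refl's index order."""
    from .cell import AtomSite, Structure
    from .simulate import GroundTruth

    n_engine = None
    sites = []
    phase_map = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts[0] == "n_engine":
                n_engine = int(parts[1])
            elif parts[0] == "site":
                sites.append(AtomSite(float(parts[1]), float(parts[2]),
                                      float(parts[3]), float(parts[4]),
                                      parts[5] if len(parts) > 5 else ""))
            continue
        parts = line.split()
        phase_map[(int(parts[0]), int(parts[1]), int(parts[2]))] = (
            np.radians(float(parts[3])))
    phases = np.array([phase_map[tuple(int(v) for v in hkl)]
                       for hkl in refl.indices])
    return GroundTruth(Structure(refl.cell, sites),
                       np.mod(phases, 2.0 * np.pi), n_engine)


def _canonicalize(indices: np.ndarray, values: np.ndarray):
    """Collapse to the Friedel-unique hemisphere, averaging duplicates."""
    seen: dict[tuple, list[float]] = {}
    for hkl, v in zip(indices, values):
        key = tuple(int(x) for x in hkl)
        first = next((c for c in key if c != 0), 0)
        if first < 0:
            key = tuple(-x for x in key)
        if key == (0, 0, 0):
            continue
        seen.setdefault(key, []).append(float(v))
    out = sorted(seen.items())
    hkl = np.array([k for k, _ in out], dtype=np.int64)
    vals = np.array([np.mean(v) for _, v in out])
    return hkl, vals


def _shell_normalize(cell: UnitCell, indices, F, n_shells: int = 20):
    """Best-effort E-normalization of F amplitudes by resolution-shell
    averaging: |E|^2 = |F|^2 / <|F|^2>_shell in equal-volume 1/d^3 shells."""
    gcell = cell.gemmi()
    inv_d3 = np.array([1.0 / gcell.calculate_d(tuple(int(v) for v in h)) ** 3
                       for h in indices])
    edges = np.quantile(inv_d3, np.linspace(0, 1, n_shells + 1))
    which = np.clip(np.searchsorted(edges, inv_d3, side="right") - 1,
                    0, n_shells - 1)
    F2 = np.asarray(F) ** 2
    E = np.empty_like(F2)
    for s in range(n_shells):
        sel = which == s
        if sel.any():
            E[sel] = np.sqrt(F2[sel] / np.mean(F2[sel]))
    return E


def import_external(path, out_path, d_min=None) -> None:
    """Convert an MTZ or structure-factor mmCIF file to the native format.

    Uses an E column directly when present; otherwise shell-normalizes an
    amplitude (F) column.  Native text files pass through unchanged.
    """
    path = str(path)
    if path.endswith(".mtz"):
        mtz = gemmi.read_mtz_file(path)
        cell = UnitCell(mtz.cell.a, mtz.cell.b, mtz.cell.c,
                        mtz.cell.alpha, mtz.cell.beta, mtz.cell.gamma)
        labels = [c.label for c in mtz.columns]
        hkl = np.array(mtz.make_miller_array(), dtype=np.int64)
        col = next((c for c in mtz.columns if c.type == "E"), None) or next(
            (c for c in mtz.columns if c.type == "F"), None)
        if col is None:
            raise ValueError(f"no amplitude column; available: {labels}")
        vals = np.array(col, dtype=float)
        is_E = col.type == "E"
        res = mtz.resolution_high()
    elif path.endswith(".cif") or path.endswith(".ent"):
        doc = gemmi.cif.read(path)
        rb = gemmi.as_refln_blocks(doc)[0]
        c = rb.cell
        cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
        hkl = np.array(rb.make_miller_array(), dtype=np.int64)
        vals = None
        for tag in ("F_meas_au", "F_meas"):
            v = rb.make_float_array(tag)
            if v.size and not np.all(np.isnan(v)):
                vals = v
                break
        if vals is None:
            raise ValueError("no amplitude column (F_meas/F_meas_au) in "
                             f"{path}")
        is_E = False
        keep = ~np.isnan(vals)
        hkl, vals = hkl[keep], vals[keep]
        res = float(np.min([cell.d_spacing(h) for h in hkl]))
    else:  # native text: passthrough
        refl = read_reflections(path)
        write_reflections(refl, out_path)
        return
    hkl, vals = _canonicalize(hkl, vals)
    E = vals if is_E else _shell_normalize(cell, hkl, vals)
    refl = ReflectionSet(cell, hkl, E, d_min or res)
    write_reflections(refl, out_path)


def load_config(path=None, **overrides) -> PhasingConfig:
    """PhasingConfig from a flat YAML key-value file plus overrides."""
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: expected flat key-value mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    fields = {f.name for f in dataclasses.fields(PhasingConfig)}
    unknown = set(values) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PhasingConfig(**values)
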