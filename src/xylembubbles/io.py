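"""Minimal text readers/writers and run configuration.

GRO is the canonical exchange format for frames (3-decimal nm positions, a
documented lossy precision); CSV is the lossless internal format; tensor
series travel as xvg-style whitespace tables with '#'/'@' comment lines.
Every writer embeds the box (and, for tensor tables, Lz and temperature) so
round trips need no side channel.
"""
from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .phases import MonolayerFrame
from .tension import GammaCurve, IsothermPoint, PressureTensorSeries

__all__ = [
    "RunConfig",
    "read_frames",
    "write_gro",
    "write_xyz",
    "write_frame_csv",
    "read_pressure_table",
    "write_pressure_table",
    "curve_to_dict",
    "curve_from_dict",
    "write_isotherm_csv",
    "read_isotherm_csv",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Physical constants, classifier thresholds and solver settings.

    Serialisable to/from a flat YAML file; unknown keys are rejected so a
    typo never silently falls back to a default.
    """

    k_b: float = 1.380649e-23
    v_m: float = 2.99e-29
    rho_liquid: float = 1000.0
    gamma_water: Dict[float, float] = field(default_factory=lambda: {270.0: 76.3, 310.0: 70.5})
    delta_tolman: float = 0.0316
    kappa: float = 1.4
    lc_cutoff: float = 0.8
    gas_cutoff: float = 1.5
    lc_min_neighbors: int = 6
    grid_shape: Tuple[int, int] = (40, 40)
    discard_ps: float = 10_000.0
    n_blocks: int = 5
    dt_ps: float = 10.0
    t_end_ns: float = 100.0
    t_min_ns: float = 10.0
    stride_ns: float = 2.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "gamma_water" in data:
            data["gamma_water"] = {float(k): float(v) for k, v in data["gamma_water"].items()}
        if "grid_shape" in data:
            data["grid_shape"] = tuple(data["grid_shape"])
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        data = dataclasses.asdict(self)
        data["grid_shape"] = list(data["grid_shape"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def module_seed(self, module: str) -> int:
        """Deterministic per-module seed expanded from the config seed."""
        ss = np.random.SeedSequence([self.seed, abs(hash(module)) % (2**31)])
        return int(ss.generate_state(1)[0] % (2**31))


# --------------------------------------------------------------------------
# frames: GRO / XYZ / CSV
# --------------------------------------------------------------------------

def write_gro(frames, path: str, z_value: float = 0.0, lz: float = 1.0) -> None:
    """Write frame(s) as concatenated GRO blocks (positions in nm, 3 decimals)."""
    if isinstance(frames, MonolayerFrame):
        frames = [frames]
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"monolayer frame t= {fr.time:.6f}\n")
            fh.write(f"{fr.n_atoms:5d}\n")
            for i, (x, y) in enumerate(fr.coords):
                resname = str(fr.species[i]) if fr.species is not None else "LIP"
                fh.write(
                    f"{i + 1:5d}{resname[:5]:<5s}{'C6':>5s}{(i + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z_value:8.3f}\n"
                )
            fh.write(f"{fr.box_lengths[0]:10.5f}{fr.box_lengths[1]:10.5f}{lz:10.5f}\n")


def _read_gro(path: str) -> List[MonolayerFrame]:
    frames: List[MonolayerFrame] = []
    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        raise ValueError(f"{path}: empty GRO file")
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        title = lines[k]
        time = len(frames) * 1.0
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (IndexError, ValueError):
                pass
        try:
            natoms = int(lines[k + 1])
        except (IndexError, ValueError):
            raise ValueError(f"{path}:{k + 2}: expected atom count")
        if k + 2 + natoms >= len(lines):
            raise ValueError(f"{path}:{k + 2}: truncated frame (expected {natoms} atoms + box line)")
        coords = np.empty((natoms, 2))
        species = []
        for i in range(natoms):
            line = lines[k + 2 + i]
            try:
                # fixed-width GRO columns; velocities (if present) are ignored
                coords[i, 0] = float(line[20:28])
                coords[i, 1] = float(line[28:36])
                species.append(line[5:10].strip())
            except (IndexError, ValueError):
                raise ValueError(f"{path}:{k + 3 + i}: malformed GRO atom record: {line.rstrip()!r}")
        box_line = lines[k + 2 + natoms].split()
        if len(box_line) < 2:
            raise ValueError(f"{path}:{k + 3 + natoms}: missing box line")
        frames.append(
            MonolayerFrame(
                coords=coords,
                box_lengths=(float(box_line[0]), float(box_line[1])),
                time=time,
                species=np.array(species),
            )
        )
        k += 2 + natoms + 1
    return frames


def write_xyz(frames, path: str) -> None:
    """XYZ-style frames; positions in nm, box and time on the comment line."""
    if isinstance(frames, MonolayerFrame):
        frames = [frames]
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{fr.n_atoms}\n")
            fh.write(f"box= {fr.box_lengths[0]:.9f} {fr.box_lengths[1]:.9f} t= {fr.time:.9f}\n")
            for i, (x, y) in enumerate(fr.coords):
                sp = str(fr.species[i]) if fr.species is not None else "C"
                fh.write(f"{sp} {x:.9f} {y:.9f} 0.0\n")


def _read_xyz(path: str) -> List[MonolayerFrame]:
    frames: List[MonolayerFrame] = []
    with open(path) as fh:
        lines = [ln for ln in fh.readlines()]
    if not any(line.strip() for line in lines):
        raise ValueError(f"{path}: empty XYZ file")
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            natoms = int(lines[k])
        except ValueError:
            raise ValueError(f"{path}:{k + 1}: expected atom count")
        comment = lines[k + 1]
        toks = comment.split()
        box = None
        time = float(len(frames))
        if "box=" in comment:
            i = toks.index("box=")
            box = (float(toks[i + 1]), float(toks[i + 2]))
        if "t=" in comment:
            time = float(toks[toks.index("t=") + 1])
        if box is None:
            raise ValueError(f"{path}:{k + 2}: XYZ comment line must carry 'box= Lx Ly'")
        coords = np.empty((natoms, 2))
        species = []
        for i in range(natoms):
            parts = lines[k + 2 + i].split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{k + 3 + i}: malformed XYZ record")
            species.append(parts[0])
            coords[i] = (float(parts[1]), float(parts[2]))
        frames.append(MonolayerFrame(coords=coords, box_lengths=box, time=time, species=np.array(species)))
        k += 2 + natoms
    return frames


def write_frame_csv(frame: MonolayerFrame, path: str, labels: Optional[Sequence[str]] = None) -> None:
    """Lossless CSV: '# box'/'# t' comment header then atom_id,x,y,species[,label]."""
    with open(path, "w") as fh:
        fh.write(f"# box {float(frame.box_lengths[0])!r} {float(frame.box_lengths[1])!r}\n")
        fh.write(f"# t {float(frame.time)!r}\n")
        fh.write(f"# leaflet {frame.leaflet_id}\n")
        cols = "atom_id,x,y,species" + (",label" if labels is not None else "")
        fh.write(cols + "\n")
        for i, (x, y) in enumerate(frame.coords):
            sp = str(frame.species[i]) if frame.species is not None else "LIP"
            row = f"{i},{float(x)!r},{float(y)!r},{sp}"
            if labels is not None:
                row += f",{labels[i]}"
            fh.write(row + "\n")


def _read_csv_frame(path: str) -> List[MonolayerFrame]:
    box = None
    time = 0.0
    leaflet = 0
    with open(path) as fh:
        raw = fh.readlines()
    if not any(line.strip() for line in raw):
        raise ValueError(f"{path}: empty CSV file")
    body_start = 0
    for i, line in enumerate(raw):
        if line.startswith("#"):
            toks = line[1:].split()
            if toks and toks[0] == "box":
                box = (float(toks[1]), float(toks[2]))
            elif toks and toks[0] == "t":
                time = float(toks[1])
            elif toks and toks[0] == "leaflet":
                leaflet = int(toks[1])
        else:
            body_start = i
            break
    if box is None:
        raise ValueError(f"{path}: CSV frame requires a '# box Lx Ly' header line")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(raw[body_start:])), float_precision="round_trip")
    for col in ("x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: CSV frame must have columns x,y (got {list(df.columns)})")
    species = df["species"].to_numpy() if "species" in df.columns else None
    return [
        MonolayerFrame(
            coords=df[["x", "y"]].to_numpy(dtype=float),
            box_lengths=box,
            time=time,
            species=species,
            leaflet_id=leaflet,
        )
    ]


def read_frames(path: str, format: Optional[str] = None) -> List[MonolayerFrame]:
    """Read monolayer frame(s) from GRO, XYZ or CSV (format inferred from extension)."""
    if format is None:
        format = os.path.splitext(path)[1].lstrip(".").lower()
    if format == "gro":
        return _read_gro(path)
    if format == "xyz":
        return _read_xyz(path)
    if format == "csv":
        return _read_csv_frame(path)
    raise ValueError(f"unsupported frame format {format!r} (expected gro, xyz or csv)")


# --------------------------------------------------------------------------
# pressure-tensor tables (xvg-style)
# --------------------------------------------------------------------------

def write_pressure_table(series: PressureTensorSeries, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# diagonal pressure-tensor series\n")
        fh.write(f"# lz_nm {float(series.lz)!r}\n")
        fh.write(f"# temperature_K {float(series.temperature)!r}\n")
        fh.write('@ title "pressure tensor"\n')
        fh.write("@ xaxis label \"time (ps)\"\n")
        for t, a, b, c in zip(series.times, series.p_xx, series.p_yy, series.p_zz):
            fh.write(f"{float(t)!r} {float(a)!r} {float(b)!r} {float(c)!r}\n")


def read_pressure_table(
    path: str,
    lz: Optional[float] = None,
    temperature: Optional[float] = None,
    columns: Tuple[int, int, int, int] = (0, 1, 2, 3),
) -> PressureTensorSeries:
    """Read an xvg-style whitespace table (time, P_xx, P_yy, P_zz).

    '#'/'@' lines are comments; '# lz_nm'/'# temperature_K' header comments
    supply Lz and T unless overridden by the arguments.  Ragged rows raise
    with their line number.
    """
    rows: List[List[float]] = []
    ncol = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith(("#", "@")):
                toks = s[1:].split()
                if len(toks) >= 2 and toks[0] == "lz_nm" and lz is None:
                    lz = float(toks[1])
                if len(toks) >= 2 and toks[0] == "temperature_K" and temperature is None:
                    temperature = float(toks[1])
                continue
            parts = s.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric entry in table row: {s!r}")
            if ncol is None:
                ncol = len(vals)
                if ncol < 4:
                    raise ValueError(
                        f"{path}:{lineno}: need >= 4 numeric columns (time, Pxx, Pyy, Pzz), got {ncol}"
                    )
            elif len(vals) != ncol:
                raise ValueError(f"{path}:{lineno}: ragged row ({len(vals)} columns, expected {ncol})")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    if lz is None:
        raise ValueError(f"{path}: Lz not found in header comments and not supplied")
    arr = np.array(rows)
    it, ix, iy, iz = columns
    return PressureTensorSeries(
        times=arr[:, it], p_xx=arr[:, ix], p_yy=arr[:, iy], p_zz=arr[:, iz],
        lz=lz, temperature=temperature if temperature is not None else 300.0,
    )


# --------------------------------------------------------------------------
# curves and isotherms
# --------------------------------------------------------------------------

def curve_to_dict(curve: GammaCurve) -> dict:
    return {
        "c": curve.c, "a1": curve.a1, "mu1": curve.mu1, "s1": curve.s1,
        "a2": curve.a2, "mu2": curve.mu2, "s2": curve.s2,
        "domain": list(curve.domain), "n_lipids": curve.n_lipids,
    }


def curve_from_dict(data: dict) -> GammaCurve:
    return GammaCurve(
        c=data["c"], a1=data["a1"], mu1=data["mu1"], s1=data["s1"],
        a2=data["a2"], mu2=data["mu2"], s2=data["s2"],
        domain=tuple(data["domain"]), n_lipids=data.get("n_lipids", 1e5),
    )


def write_isotherm_csv(points: Sequence[IsothermPoint], path: str) -> None:
    df = pd.DataFrame(
        {
            "apl_nm2": [p.apl for p in points],
            "gamma_mN_m": [p.gamma_md for p in points],
            "gamma_sd_mN_m": [p.gamma_sd for p in points],
            "pi_mN_m": [p.pi_md for p in points],
            "temperature_K": [p.temperature for p in points],
        }
    )
    df.to_csv(path, index=False)


def read_isotherm_csv(path: str) -> List[IsothermPoint]:
    df = pd.read_csv(path)
    return [
        IsothermPoint(
            apl=row.apl_nm2, gamma_md=row.gamma_mN_m, gamma_sd=row.gamma_sd_mN_m,
            pi_md=row.pi_mN_m, temperature=row.temperature_K,
        )
        for row in df.itertuples()
    ]
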