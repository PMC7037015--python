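"""Configuration, CSV, and JCAMP-DX readers/writers.

File conventions: CSV is UTF-8, comma separated, '.' decimal, all times in
seconds; ppm axes are written descending; Hz axes are offsets from the
transmitter.  Spin systems load from a small YAML schema (see README).
The JCAMP-DX writer emits a plain AFFN ``(X++(Y..Y))`` 1D record readable
by common NMR viewers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .recon import Spectrum
from .spin_system import SpinSystem

__all__ = [
    "load_spin_system",
    "save_spin_system",
    "write_spectrum_csv",
    "write_spectrum_jcampdx",
    "read_spectrum_jcampdx",
    "read_intensity_csv",
    "write_series",
    "read_series",
    "RunConfig",
]

_TIME_SUFFIX = {"s": 1.0, "ms": 1e-3, "us": 1e-6}


def parse_time_s(value) -> float:
    """Parse a time that may carry a unit suffix ('16.2 ms') into seconds."""
    if isinstance(value, (int, float)):
        return float(value)
    m = re.fullmatch(r"\s*([-+0-9.eE]+)\s*(s|ms|us)?\s*", str(value))
    if not m:
        raise ValueError(f"cannot parse time {value!r}")
    return float(m.group(1)) * _TIME_SUFFIX[m.group(2) or "s"]


def load_spin_system(path) -> SpinSystem:
    """Load a spin system from its YAML description."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "spins" not in data:
        raise ValueError(f"{path}: expected a mapping with a 'spins' list")
    return SpinSystem.from_dict(data)


def save_spin_system(system: SpinSystem, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(system.to_dict(), fh, sort_keys=False)


def write_spectrum_csv(spec: Spectrum, path) -> None:
    """Spectrum as CSV with ppm, Hz, real, imag columns (descending ppm)."""
    pd.DataFrame(
        {
            "ppm": spec.axis_ppm,
            "hz": spec.axis_hz,
            "real": spec.values.real,
            "imag": spec.values.imag,
        }
    ).to_csv(path, index=False)


def write_spectrum_jcampdx(spec: Spectrum, path, title: str = "zsrelax spectrum") -> None:
    """Write the real part of a 1D spectrum as JCAMP-DX (AFFN X++(Y..Y)).

    The X axis is Hz (##XUNITS=HZ) in the spectrum's stored (descending)
    order, i.e. with a negative DELTAX.
    """
    if len(spec.values) == 0:
        raise ValueError("cannot write an empty spectrum")
    x = spec.axis_hz
    y = spec.values.real
    n = len(x)
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=HZ",
        "##YUNITS=ARBITRARY UNITS",
        f"##NPOINTS={n}",
        f"##FIRSTX={x[0]:.8g}",
        f"##LASTX={x[-1]:.8g}",
        f"##DELTAX={(x[-1] - x[0]) / max(n - 1, 1):.8g}",
        "##XFACTOR=1",
        "##YFACTOR=1",
        f"##FIRSTY={y[0]:.8g}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, n, per_line):
        chunk = y[i : i + per_line]
        lines.append(" ".join([f"{x[i]:.8g}"] + [f"{v:.8g}" for v in chunk]))
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_spectrum_jcampdx(path) -> Spectrum:
    """Read back a 1D AFFN (X++(Y..Y)) JCAMP-DX record written by this module."""
    text = Path(path).read_text(encoding="utf-8")
    fields = dict(re.findall(r"^##([^=\n]+)=(.*)$", text, flags=re.M))
    if "XYDATA" not in fields:
        raise ValueError(f"{path}: no ##XYDATA record")
    n = int(fields["NPOINTS"])
    first_x = float(fields["FIRSTX"])
    last_x = float(fields["LASTX"])
    yfac = float(fields.get("YFACTOR", 1) or 1)
    body = text.split("##XYDATA", 1)[1].split("\n", 1)[1].split("##END")[0]
    ys: list[float] = []
    for line in body.strip().splitlines():
        vals = [float(v) for v in line.split()]
        ys.extend(vals[1:])  # first token on each line is the X check value
    if len(ys) != n:
        raise ValueError(f"{path}: expected {n} points, found {len(ys)}")
    axis_hz = np.linspace(first_x, last_x, n)
    return Spectrum(
        axis_hz=axis_hz,
        axis_ppm=axis_hz,  # ppm scale unknown from a bare Hz record
        values=np.array(ys) * yfac,
        metadata={"source": str(path)},
    )


def read_intensity_csv(path):
    """Read a delay/intensity table: header row, first column delays (s).

    Returns ``(delays, DataFrame)`` where the DataFrame holds one signed
    intensity column per peak.  Raises on a missing header or any
    non-numeric cell, naming the offending row and column.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline()
        header = [h.strip() for h in header_line.rstrip("\n").split(",")]
        if not header or all(_is_number(h) for h in header):
            raise ValueError(f"{path}: missing header row")
        rows = []
        for i, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(",")
            if len(cells) != len(header):
                raise ValueError(f"{path}: row {i} has {len(cells)} cells, expected {len(header)}")
            parsed = []
            for name, cell in zip(header, cells):
                if not _is_number(cell):
                    raise ValueError(f"{path}: non-numeric cell at row {i}, column {name!r}")
                parsed.append(float(cell))
            rows.append(parsed)
    df = pd.DataFrame(rows, columns=header)
    delays = df.iloc[:, 0].to_numpy()
    return delays, df.iloc[:, 1:]


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_series(series, outdir) -> None:
    """One time-domain CSV per delay plus a YAML manifest."""
    from .sequence import RelaxationSeries  # noqa: F401  (typing aid)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sw = series.spectral_width_hz
    t = np.arange(series.fids.shape[1]) / sw
    names = []
    for i, (delay, fid) in enumerate(zip(series.delays, series.fids)):
        name = f"fid_{i:03d}.csv"
        names.append(name)
        pd.DataFrame({"t_s": t, "real": fid.real, "imag": fid.imag}).to_csv(
            outdir / name, index=False
        )
    manifest = {
        "delays_s": [float(d) for d in series.delays],
        "files": names,
        "mode": series.mode,
        "experiment": series.experiment,
        "metadata": {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in series.metadata.items()
        },
    }
    with open(outdir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_series(indir):
    """Inverse of :func:`write_series`."""
    from .sequence import RelaxationSeries

    indir = Path(indir)
    with open(indir / "manifest.yaml", "r", encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    fids = []
    for name in manifest["files"]:
        df = pd.read_csv(indir / name)
        fids.append(df["real"].to_numpy() + 1j * df["imag"].to_numpy())
    return RelaxationSeries(
        delays=np.array(manifest["delays_s"], dtype=float),
        fids=np.array(fids),
        mode=manifest["mode"],
        experiment=manifest["experiment"],
        metadata=manifest.get("metadata", {}),
    )


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulate->reconstruct->fit run."""

    sample: str = "bromobutane"
    experiment: str = "IR"
    mode: str = "zs"
    apodization_hz: float = 0.0
    zero_fill_factor: int = 2
    min_height_fraction: float = 0.2
    noise_sigma: float = 0.0
    seed: int = 0
    deshimmed: bool = False
    outdir: str = "."
    extra: dict = dc_field(default_factory=dict)

    def to_yaml(self, path) -> None:
        d = {k: v for k, v in self.__dict__.items()}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))
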