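"""Plain-text readers/writers and scan preprocessing.

Dataset files are matrices with the wavenumber axis (cm^-1) as the first
row and the delay axis (ps) as the first column; cells are difference
absorbance in mOD. Comma- and tab-separated dialects are sniffed on read.
Comment lines start with ``#`` and carry channel/unit metadata. Values are
printed with 17 significant digits so write -> read round trips are
bit-identical for float64.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .dataset import TADataset
from .simulate import TitrationSeries
from .specdens import DipoleTrajectory

__all__ = [
    "ScanStack",
    "read_dataset",
    "write_dataset",
    "read_trajectory",
    "write_trajectory",
    "read_titration",
    "write_titration",
    "combine_scans",
    "subtract_background",
    "reproducibility_block",
]

_FMT = "%.17g"


def _sniff_delimiter(line: str) -> str:
    return "," if line.count(",") > line.count("\t") else "\t"


def _parse_header(lines):
    meta = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            meta[key.strip()] = val.strip()
    return meta


def read_dataset(path) -> TADataset:
    """Read a delay x wavenumber matrix file (sniffed comma/tab dialect)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = fh.read().splitlines()
    header = [ln for ln in raw if ln.startswith("#")]
    body = [(i + 1, ln) for i, ln in enumerate(raw)
            if ln.strip() and not ln.startswith("#")]
    if len(body) < 2:
        raise ValueError(f"{path}: no data rows")
    delim = _sniff_delimiter(body[0][1])
    first = body[0][1].split(delim)
    try:
        wavenumbers = np.array([float(x) for x in first[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: line {body[0][0]}: bad wavenumber row") from exc
    n_cols = len(first)
    delays, rows = [], []
    for lineno, ln in body[1:]:
        parts = ln.split(delim)
        if len(parts) != n_cols:
            raise ValueError(
                f"{path}: line {lineno}: expected {n_cols} fields, got {len(parts)}"
            )
        try:
            delays.append(float(parts[0]))
            rows.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
    delays = np.asarray(delays)
    values = np.asarray(rows)
    for name, ax in (("delay", delays), ("wavenumber", wavenumbers)):
        d = np.diff(ax)
        if ax.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            inc = d > 0
            bad = int(np.argmin(inc if inc.sum() >= (~inc).sum() else ~inc)) + 2
            raise ValueError(f"{path}: non-monotone {name} axis at entry {bad}")
    meta = _parse_header(header)
    channel = meta.pop("channel", "iso")
    return TADataset(delays, wavenumbers, values, channel=channel, meta=meta)


def write_dataset(data: TADataset, path, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# photokin transient-absorption dataset\n")
        fh.write(f"# channel: {data.channel}\n")
        fh.write("# units: delays ps, wavenumbers cm-1, values mOD\n")
        for key in ("channel_map",):
            if key in data.meta:
                fh.write(f"# {key}: {data.meta[key]}\n")
        fh.write(delimiter.join(["delay_ps\\wn"] +
                                [_FMT % w for w in data.wavenumbers]) + "\n")
        for t, row in zip(data.delays, data.values):
            fh.write(delimiter.join([_FMT % t] + [_FMT % v for v in row]) + "\n")


def read_trajectory(path) -> DipoleTrajectory:
    """Read a dipole trajectory: metadata comments, then one 3-vector per line."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = fh.read().splitlines()
    meta = _parse_header([ln for ln in raw if ln.startswith("#")])
    rows = []
    for i, ln in enumerate(raw):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) != 3:
            raise ValueError(f"{path}: line {i + 1}: expected 3 dipole components")
        rows.append([float(x) for x in parts])
    return DipoleTrajectory(
        dt=float(meta.get("dt_fs", 1.0)),
        dipole=np.asarray(rows),
        temperature=float(meta.get("temperature_K", 300.0)),
        volume=float(meta.get("volume_nm3", 0.3)),
        isotope_label=meta.get("isotope", ""),
    )


def write_trajectory(traj: DipoleTrajectory, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# photokin dipole trajectory (e*Angstrom)\n")
        fh.write(f"# dt_fs: {_FMT % traj.dt}\n")
        fh.write(f"# temperature_K: {_FMT % traj.temperature}\n")
        fh.write(f"# volume_nm3: {_FMT % traj.volume}\n")
        fh.write(f"# isotope: {traj.isotope_label}\n")
        for row in traj.dipole:
            fh.write(" ".join(_FMT % x for x in row) + "\n")


def read_titration(path) -> TitrationSeries:
    """Two- or three-column text: pH, amplitude [, error]."""
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, ln in enumerate(fh):
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.replace(",", " ").split()
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}: line {i + 1}: expected 2 or 3 columns")
            rows.append([float(x) for x in parts])
    arr = np.asarray(rows)
    errors = arr[:, 2] if arr.shape[1] == 3 else None
    return TitrationSeries(arr[:, 0], arr[:, 1], errors)


def write_titration(series: TitrationSeries, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# pH  amplitude_mOD" +
                 ("  error_mOD" if series.errors is not None else "") + "\n")
        for i in range(series.ph_values.size):
            cols = [series.ph_values[i], series.amplitudes[i]]
            if series.errors is not None:
                cols.append(series.errors[i])
            fh.write(" ".join(_FMT % c for c in cols) + "\n")


# ---------------------------------------------------------------------------
# Scan combination and background handling
# ---------------------------------------------------------------------------


@dataclass
class ScanStack:
    """Repeated scans of the same measurement on identical grids."""

    scans: list

    def __post_init__(self):
        if len(self.scans) < 1:
            raise ValueError("need at least one scan")
        ref = self.scans[0]
        for s in self.scans[1:]:
            if not ref.same_grids(s):
                raise ValueError("scans have differing axes")


def combine_scans(stack, trim_fraction: float = 0.10):
    """Per-point symmetrically trimmed mean over repeated scans.

    ``trim_fraction`` is the total fraction of values discarded per point
    (half per tail; default 0.10 i.e. 5% per tail), emulating the outlier
    median-filtering applied to individually saved scans. Invariant under
    scan permutation. Returns a combined :class:`TADataset` whose meta
    records the number of values rejected per point.
    """
    if not isinstance(stack, ScanStack):
        stack = ScanStack(list(stack))
    if not (0.0 <= trim_fraction < 0.5):
        raise ValueError("trim_fraction must be in [0, 0.5)")
    cube = np.stack([s.values for s in stack.scans])  # scans x t x wn
    n = cube.shape[0]
    k = int(n * trim_fraction / 2.0)  # values cut per tail
    if 2 * k >= n:
        raise ValueError("trim removes all values")
    srt = np.sort(cube, axis=0)
    kept = srt[k: n - k]
    combined = kept.mean(axis=0)
    ref = stack.scans[0]
    meta = dict(ref.meta)
    meta.update(n_scans=n, rejected_per_point=2 * k, trim_fraction=trim_fraction)
    return TADataset(ref.delays.copy(), ref.wavenumbers.copy(), combined,
                     channel=ref.channel, meta=meta)


def subtract_background(data: TADataset, background_delays) -> TADataset:
    """Subtract the per-wavenumber mean over the given background delays.

    Background rows are typically recorded far before time zero (around
    -60 ps) to sample the static signal free of perturbed free-induction
    decay. Delays are matched to the grid within 1e-9 ps.
    """
    bg = np.atleast_1d(np.asarray(background_delays, dtype=float))
    mask = np.any(np.abs(data.delays[:, None] - bg[None, :]) < 1e-9, axis=1)
    if not mask.any():
        raise ValueError("no delays match the requested background delays")
    baseline = data.values[mask].mean(axis=0)
    out = data.copy()
    out.values = out.values - baseline[None, :]
    out.meta["background_delays"] = [float(b) for b in bg]
    return out


def reproducibility_block(config_text: str = "", seed=None, extra=None) -> str:
    """Provenance block written into CLI reports (config hash, seed, version)."""
    from . import __version__

    digest = hashlib.sha256(config_text.encode()).hexdigest()[:16]
    lines = [
        "# --- reproducibility ---",
        f"# photokin version: {__version__}",
        f"# config sha256[:16]: {digest}",
        f"# seed: {seed}",
    ]
    if extra:
        lines += [f"# {k}: {v}" for k, v in extra.items()]
    return "\n".join(lines) + "\n"
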