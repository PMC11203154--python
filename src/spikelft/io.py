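"""File formats and bundle management.

Raster file: delimited text (comma or tab), rows = neurons, columns = time
bins, cells strictly 0/1, with '#'-prefixed header lines::

    # tau_ms=1.0
    # t0_bin=0
    # labels=n0,n1,n2

Hypermatrix bundle: a directory holding ``kernel.csv`` plus derived-matrix
CSVs and a ``meta.json`` manifest with tau, representation, provenance and
per-file sha256 checksums.  Floats are written with 17 significant digits so
a round-trip is bit-faithful.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .kernelspace import BinaryKernel
from .observables import correlation_set, first_order

__all__ = [
    "RasterParseError",
    "read_raster",
    "write_raster",
    "write_hypermatrix",
    "read_hypermatrix",
    "read_matrix",
    "write_matrix",
    "read_action_parameters",
    "write_action_parameters",
]

_FLOAT_FMT = "%.17g"


class RasterParseError(ValueError):
    """Malformed raster file; message carries line/column information."""


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_raster(path) -> BinaryKernel:
    """Parse a raster file into a :class:`BinaryKernel`.

    Rejects any cell not exactly '0' or '1', naming the offending row and
    column.  A missing ``tau_ms`` header raises.
    """
    path = Path(path)
    tau_ms: Optional[float] = None
    t0_bin = 0
    labels: tuple[str, ...] = ()
    rows: list[list[int]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key = key.strip()
                    if key == "tau_ms":
                        tau_ms = float(val)
                    elif key == "t0_bin":
                        t0_bin = int(val)
                    elif key == "labels":
                        labels = tuple(s.strip() for s in val.split(","))
                continue
            delim = _sniff_delimiter(line)
            cells = line.split(delim)
            row = []
            for col, cell in enumerate(cells, start=1):
                cell = cell.strip()
                if cell not in ("0", "1"):
                    raise RasterParseError(
                        f"{path}: line {lineno}, column {col}: "
                        f"cell {cell!r} is not 0 or 1"
                    )
                row.append(int(cell))
            rows.append(row)
    if tau_ms is None:
        raise RasterParseError(f"{path}: missing '# tau_ms=' header")
    if not rows:
        raise RasterParseError(f"{path}: no data rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise RasterParseError(f"{path}: ragged rows (widths {sorted(widths)})")
    return BinaryKernel(values=np.array(rows, dtype=np.uint8), tau_ms=tau_ms,
                        neuron_labels=labels, time_origin=t0_bin)


def write_raster(k: BinaryKernel, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(f"# tau_ms={k.tau_ms!r}\n")
        fh.write(f"# t0_bin={k.time_origin}\n")
        fh.write("# labels=" + ",".join(k.neuron_labels) + "\n")
        for row in k.values:
            fh.write(",".join(str(int(v)) for v in row) + "\n")
    return path


def write_matrix(arr: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.atleast_2d(arr), delimiter=",", fmt=_FLOAT_FMT)
    return path


def read_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(Path(path), delimiter=",", ndmin=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_hypermatrix(k: BinaryKernel, out_dir, include_spin: bool = True,
                      provenance: Optional[list] = None) -> Path:
    """Serialize a kernel and its derived observables as a bundle directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cs = correlation_set(k)
    fo = first_order(k)
    files = {"kernel.csv": None}
    write_raster(k, out / "kernel.csv")
    write_matrix(cs.phi, out / "phi.csv")
    write_matrix(cs.pi, out / "pi.csv")
    write_matrix(fo.row_rates, out / "f.csv")
    write_matrix(fo.col_activity, out / "omega.csv")
    write_matrix(cs.c_star_binary, out / "c_star.csv")
    write_matrix(cs.q_star_binary, out / "q_star.csv")
    names = ["kernel.csv", "phi.csv", "pi.csv", "f.csv", "omega.csv",
             "c_star.csv", "q_star.csv"]
    if include_spin:
        write_matrix(cs.spin_c, out / "c.csv")
        write_matrix(cs.spin_q, out / "q.csv")
        names += ["c.csv", "q.csv"]
    meta = {
        "version": __version__,
        "representation": "binary",
        "tau_ms": k.tau_ms,
        "t0_bin": k.time_origin,
        "offset": fo.offset_binary,
        "provenance": provenance or [],
        "checksums": {name: _sha256(out / name) for name in names},
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out


def read_hypermatrix(bundle_dir, verify: bool = True) -> dict:
    """Load a bundle; derived matrices absent on disk are recomputed.

    Returns a dict with keys ``kernel`` (BinaryKernel), ``phi``, ``pi``,
    ``f``, ``omega`` (+ spin/connected matrices when present) and ``meta``.
    Checksum mismatches raise unless ``verify`` is False.
    """
    bundle = Path(bundle_dir)
    meta = json.loads((bundle / "meta.json").read_text())
    if verify:
        for name, digest in meta.get("checksums", {}).items():
            actual = _sha256(bundle / name)
            if actual != digest:
                raise ValueError(
                    f"checksum mismatch for {name}: {actual} != {digest}"
                )
    kernel = read_raster(bundle / "kernel.csv")
    out = {"kernel": kernel, "meta": meta}
    for name in ("phi", "pi", "f", "omega", "c", "q", "c_star", "q_star"):
        path = bundle / f"{name}.csv"
        if path.exists():
            arr = read_matrix(path)
            out[name] = arr.ravel() if name in ("f", "omega") else arr
    if "phi" not in out:
        cs = correlation_set(kernel)
        fo = first_order(kernel)
        out.update(phi=cs.phi, pi=cs.pi, f=fo.row_rates, omega=fo.col_activity)
    return out


def write_action_parameters(p, out_dir) -> Path:
    from .action import ActionParameters  # local import to avoid cycle
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(p.potential, out / "A.csv")
    write_matrix(p.kinetic, out / "B.csv")
    write_matrix(p.input_kernel, out / "I.csv")
    params = {"lam": p.lam, "representation": p.representation}
    (out / "params.json").write_text(json.dumps(params, indent=2))
    return out


def read_action_parameters(in_dir):
    from .action import ActionParameters
    src = Path(in_dir)
    params = json.loads((src / "params.json").read_text())
    return ActionParameters(
        potential=read_matrix(src / "A.csv"),
        kinetic=read_matrix(src / "B.csv"),
        input_kernel=read_matrix(src / "I.csv"),
        lam=params.get("lam", 1.0),
        representation=params.get("representation", "spin"),
    )
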