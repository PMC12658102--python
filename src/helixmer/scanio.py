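"""Readers and writers for external formats.

Covers: the documented plain-text scan format (one file per scan plus a
YAML manifest grouping scans into sets), a lenient reader for
Beckman-style two-line-header velocity scans, PDB / multi-model PDB
structure ensembles (via biotite, Å converted to nm on read, residue
numbering kept verbatim), c(s) distributions as two-column TSV with a
JSON sidecar, and provenance-stamped JSON/TSV reports.

All readers validate and reject malformed input rather than coercing
it; every writer/reader pair round-trips.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .cs_inversion import CsDistribution
from .lamm_forward import ScanSet
from .traj_analysis import TrajectoryEnsemble

__all__ = [
    "write_scan_set",
    "read_scan_set",
    "read_scan_file",
    "read_models",
    "write_models",
    "write_cs_distribution",
    "read_cs_distribution",
    "write_report",
]

SCAN_MAGIC = "# helixmer scan v1"


class IoError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scan files
# ---------------------------------------------------------------------------

_HEADER_FIELDS = (
    ("time_s", float),
    ("rpm", float),
    ("temperature_C", float),
    ("pathlength_mm", float),
    ("wavelength_nm", float),
    ("meniscus_cm", float),
    ("bottom_cm", float),
)


def write_scan_set(scans: ScanSet, out_dir: str | Path, label: str = "set") -> Path:
    """Write one file per scan plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for i, (t, sig) in enumerate(zip(scans.times_s, scans.signal_au)):
        name = f"{label}_scan{i:04d}.txt"
        lines = [
            SCAN_MAGIC,
            f"time_s: {t:.6g}",
            f"rpm: {scans.rpm:.6g}",
            f"temperature_C: {scans.temperature_c:.6g}",
            f"pathlength_mm: {scans.pathlength_cm * 10.0:.6g}",
            f"wavelength_nm: {scans.wavelength_nm:.6g}",
            f"meniscus_cm: {scans.meniscus_cm:.6g}",
            f"bottom_cm: {scans.bottom_cm:.6g}",
            "radius_cm\tsignal_AU",
        ]
        lines += [f"{r:.6f}\t{v:.8e}" for r, v in zip(scans.radii_cm, sig)]
        (out / name).write_text("\n".join(lines) + "\n")
        files.append(name)
    manifest = out / f"{label}_manifest.yaml"
    manifest.write_text(
        yaml.safe_dump({"label": label or scans.label, "scans": files}, sort_keys=False)
    )
    return manifest


def read_scan_file(path: str | Path, lenient: bool = False) -> dict:
    """Read one scan file; returns header dict + radius/signal arrays."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if lenient:
        return _read_beckman_scan(path, lines)
    if not lines or lines[0].strip() != SCAN_MAGIC:
        raise IoError(f"{path}: not a helixmer scan file (missing {SCAN_MAGIC!r})")
    header: dict = {}
    i = 1
    while i < len(lines) and ":" in lines[i]:
        key, _, val = lines[i].partition(":")
        header[key.strip()] = val.strip()
        i += 1
    for key, conv in _HEADER_FIELDS:
        if key not in header:
            raise IoError(f"{path}: missing header field {key!r}")
        header[key] = conv(header[key])
    if i >= len(lines) or not lines[i].startswith("radius_cm"):
        raise IoError(f"{path}: missing column header line")
    i += 1
    radii, signal = [], []
    for row_no, line in enumerate(lines[i:], start=i + 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            raise IoError(f"{path}: malformed data row {row_no}: {line!r}")
        r, v = float(parts[0]), float(parts[1])
        if not np.isfinite(v):
            raise IoError(f"{path}: non-finite signal at row {row_no}")
        if radii and r <= radii[-1]:
            raise IoError(
                f"{path}: radii not strictly increasing at row {row_no} "
                f"({r} after {radii[-1]})"
            )
        radii.append(r)
        signal.append(v)
    header["radius_cm"] = np.array(radii)
    header["signal_AU"] = np.array(signal)
    return header


def _read_beckman_scan(path: Path, lines: list[str]) -> dict:
    """Lenient reader for Beckman-style two-line headers:
    a free-text description line, then
    ``<type> <cell> <temperature> <rpm> <time_s> <w2t> <wavelength> ...``."""
    if len(lines) < 3:
        raise IoError(f"{path}: too short for a two-line-header scan")
    tokens = lines[1].split()
    nums = []
    for tok in tokens:
        try:
            nums.append(float(tok))
        except ValueError:
            continue
    if len(nums) < 5:
        raise IoError(f"{path}: cannot parse Beckman-style header line {lines[1]!r}")
    # cell, temperature, rpm, time, w2t[, wavelength]
    header = {
        "temperature_C": nums[1],
        "rpm": nums[2],
        "time_s": nums[3],
        "wavelength_nm": nums[5] if len(nums) > 5 else 280.0,
        "pathlength_mm": 12.0,
        "meniscus_cm": None,
        "bottom_cm": None,
    }
    radii, signal = [], []
    for row_no, line in enumerate(lines[2:], start=3):
        parts = line.split()
        if len(parts) < 2:
            continue
        r, v = float(parts[0]), float(parts[1])
        if radii and r <= radii[-1]:
            raise IoError(f"{path}: radii not strictly increasing at row {row_no}")
        radii.append(r)
        signal.append(v)
    header["radius_cm"] = np.array(radii)
    header["signal_AU"] = np.array(signal)
    return header


def read_scan_set(
    source: str | Path | Sequence[str | Path], lenient: bool = False
) -> ScanSet:
    """Assemble a ScanSet from a manifest file or a list of scan files."""
    if isinstance(source, (str, Path)) and str(source).endswith((".yaml", ".yml")):
        manifest_path = Path(source)
        manifest = yaml.safe_load(manifest_path.read_text())
        paths = [manifest_path.parent / p for p in manifest["scans"]]
        label = manifest.get("label", "")
    elif isinstance(source, (str, Path)):
        paths = [Path(source)]
        label = ""
    else:
        paths = [Path(p) for p in source]
        label = ""
    if not paths:
        raise IoError("no scan files given")
    headers = [read_scan_file(p, lenient=lenient) for p in paths]
    headers.sort(key=lambda h: h["time_s"])
    rpms = {h["rpm"] for h in headers}
    if len(rpms) > 1:
        raise IoError(f"mixed rotor speeds in one scan set: {sorted(rpms)}")
    radii = headers[0]["radius_cm"]
    for h, p in zip(headers[1:], paths[1:]):
        if h["radius_cm"].shape != radii.shape or not np.allclose(
            h["radius_cm"], radii
        ):
            raise IoError(f"{p}: radial grid differs from the first scan")
    times = np.array([h["time_s"] for h in headers])
    if np.any(np.diff(times) <= 0):
        raise IoError("scan times are not strictly increasing across files")
    h0 = headers[0]
    meniscus = h0["meniscus_cm"] if h0["meniscus_cm"] is not None else radii[0]
    bottom = h0["bottom_cm"] if h0["bottom_cm"] is not None else radii[-1]
    return ScanSet(
        radii_cm=radii,
        times_s=times,
        signal_au=np.stack([h["signal_AU"] for h in headers]),
        rpm=float(h0["rpm"]),
        meniscus_cm=float(meniscus),
        bottom_cm=float(bottom),
        temperature_c=float(h0["temperature_C"]),
        pathlength_cm=float(h0["pathlength_mm"]) / 10.0,
        wavelength_nm=float(h0["wavelength_nm"]),
        label=label,
    )


# ---------------------------------------------------------------------------
# structure models
# ---------------------------------------------------------------------------

_ELEMENT_FROM_NAME = {"C": "C", "N": "N", "O": "O", "S": "S", "H": "H", "P": "P"}


def read_models(path: str | Path, expected_chains: Optional[int] = None) -> TrajectoryEnsemble:
    """Read a PDB / multi-model PDB into a TrajectoryEnsemble.

    Coordinates are converted Å → nm; chain IDs and (UniProt-based)
    residue numbers are preserved verbatim; each MODEL record becomes a
    frame.  Only the first altloc is kept; a missing element column is
    inferred from the atom name.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None, altloc="first")
    elements = np.array(
        [
            el if el else _ELEMENT_FROM_NAME.get(name[0], name[0])
            for el, name in zip(stack.element, stack.atom_name)
        ]
    )
    traj = TrajectoryEnsemble(
        coords_nm=np.asarray(stack.coord, dtype=float) / 10.0,
        chain_ids=np.asarray(stack.chain_id).astype(str),
        resids=np.asarray(stack.res_id).astype(int),
        resnames=np.asarray(stack.res_name).astype(str),
        atom_names=np.asarray(stack.atom_name).astype(str),
        elements=elements,
    )
    if expected_chains is not None and len(traj.chains) != expected_chains:
        raise IoError(
            f"{path}: expected {expected_chains} chains, found {len(traj.chains)} "
            f"({traj.chains})"
        )
    return traj


def write_models(traj: TrajectoryEnsemble, path: str | Path) -> Path:
    """Write a TrajectoryEnsemble as a multi-model PDB (nm → Å)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_atoms = traj.n_atoms
    arr = struc.AtomArrayStack(traj.n_frames, n_atoms)
    arr.coord = np.asarray(traj.coords_nm, dtype=np.float32) * 10.0
    arr.chain_id = traj.chain_ids.astype("U4")
    arr.res_id = traj.resids.astype(int)
    arr.res_name = traj.resnames.astype("U5")
    arr.atom_name = traj.atom_names.astype("U6")
    arr.element = traj.elements.astype("U2")
    pdb = PDBFile()
    pdb.set_structure(arr)
    path = Path(path)
    pdb.write(str(path))
    return path


# ---------------------------------------------------------------------------
# c(s) distributions and reports
# ---------------------------------------------------------------------------


def write_cs_distribution(dist: CsDistribution, prefix: str | Path) -> tuple[Path, Path]:
    """Two-column TSV (s, c(s)) plus a JSON metadata sidecar."""
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    meta = prefix.with_suffix(".json")
    lines = ["s_svedberg\tc_of_s_AU_per_S"]
    lines += [f"{s:.6f}\t{a:.8e}" for s, a in zip(dist.s_grid, dist.amplitudes)]
    tsv.write_text("\n".join(lines) + "\n")
    meta.write_text(
        json.dumps(
            {
                "f_f0": dist.f_f0,
                "regularization": dist.regularization,
                "rmsd_au": dist.rmsd_au,
                "degenerate": dist.degenerate,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return tsv, meta


def read_cs_distribution(prefix: str | Path) -> CsDistribution:
    prefix = Path(prefix)
    rows = prefix.with_suffix(".tsv").read_text().splitlines()[1:]
    data = np.array([[float(x) for x in row.split("\t")] for row in rows])
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return CsDistribution(
        s_grid=data[:, 0],
        amplitudes=data[:, 1],
        f_f0=meta["f_f0"],
        regularization=meta["regularization"],
        rmsd_au=meta["rmsd_au"],
        degenerate=meta["degenerate"],
    )


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return float(f"{float(obj):.10g}")
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_report(
    results: dict,
    path: str | Path,
    fmt: str = "json",
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> Path:
    """Serialize results with stable ordering and provenance stamps.

    Floats are written at fixed (10 significant digit) precision and
    keys sorted, so identical results give byte-identical files.  The
    report carries the package version, the seed, and a hash of the
    resolved configuration.
    """
    from . import __version__

    payload = {
        "software": {"name": "helixmer", "version": __version__},
        "seed": seed,
        "config_sha256": None
        if config is None
        else hashlib.sha256(
            json.dumps(_to_jsonable(config), sort_keys=True).encode()
        ).hexdigest(),
        "results": _to_jsonable(results),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif fmt == "tsv":
        flat = _to_jsonable(results)
        lines = ["key\tvalue"]
        for k in sorted(flat):
            lines.append(f"{k}\t{json.dumps(flat[k], sort_keys=True)}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise IoError(f"format must be json|tsv, got {fmt!r}")
    return path
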