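"""File formats, configuration and the pipeline runner.

All on-disk formats are plain text (CSV/TSV/JSON/YAML/extended XYZ)
except FLIM stacks, which are multi-frame TIFF with a JSON sidecar.
Every writer emits a ground-truth/metadata manifest JSON next to the
data file; every output of the pipeline carries the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import (
    BilayerTrajectory,
    DecayTrace,
    EmissionSpectrum,
    FLIMStack,
    ScatteringProfile,
)

__all__ = [
    "write_decay_csv", "read_decay_csv",
    "write_spectrum_csv", "read_spectrum_csv",
    "write_profile_csv", "read_profile_csv",
    "write_xyz", "read_xyz", "read_gro",
    "write_flim_stack", "read_flim_stack",
    "load_config", "config_hash", "write_manifest",
    "metric_table", "run_pipeline",
]


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_manifest(path: str | Path, metadata: Mapping[str, Any]) -> Path:
    """Write a JSON manifest next to a data file (``<path>.manifest.json``)."""
    path = Path(path)
    man = path.with_suffix(path.suffix + ".manifest.json")
    man.write_text(json.dumps(_to_jsonable(dict(metadata)), indent=2))
    return man


# ---------------------------------------------------------------------------
# CSV formats
# ---------------------------------------------------------------------------


def write_decay_csv(trace: DecayTrace, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "channel_time_ns": trace.channel_times,
            "counts": trace.counts.astype(int),
            "irf_counts": trace.irf_counts,
        }
    )
    df.to_csv(path, index=False)
    write_manifest(path, trace.metadata)
    return path


def read_decay_csv(path: str | Path) -> DecayTrace:
    df = pd.read_csv(path)
    required = {"channel_time_ns", "counts", "irf_counts"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"decay CSV missing column(s): {sorted(missing)}")
    man = Path(path).with_suffix(Path(path).suffix + ".manifest.json")
    meta = json.loads(man.read_text()) if man.exists() else {}
    return DecayTrace(
        channel_times=df["channel_time_ns"].to_numpy(),
        counts=df["counts"].to_numpy(),
        irf_counts=df["irf_counts"].to_numpy(),
        metadata=meta,
    )


def write_spectrum_csv(spectrum: EmissionSpectrum, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "intensity": spectrum.intensities}
    ).to_csv(path, index=False)
    write_manifest(path, spectrum.metadata)
    return path


def read_spectrum_csv(path: str | Path) -> EmissionSpectrum:
    df = pd.read_csv(path)
    missing = {"wavelength_nm", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"spectrum CSV missing column(s): {sorted(missing)}")
    return EmissionSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
    )


def write_profile_csv(profile: ScatteringProfile, path: str | Path) -> Path:
    path = Path(path)
    data = {"q_invA": profile.q, "intensity": profile.intensity}
    if profile.uncertainty is not None:
        data["sigma"] = profile.uncertainty
    pd.DataFrame(data).to_csv(path, index=False)
    write_manifest(path, profile.metadata)
    return path


def read_profile_csv(path: str | Path) -> ScatteringProfile:
    df = pd.read_csv(path)
    missing = {"q_invA", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing column(s): {sorted(missing)}")
    return ScatteringProfile(
        q=df["q_invA"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        uncertainty=df["sigma"].to_numpy() if "sigma" in df.columns else None,
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def write_xyz(traj: BilayerTrajectory, path: str | Path) -> Path:
    """Extended XYZ, one block per frame.

    Columns: species leaflet role mol_id x y z (Å, %.6f).  The comment
    line carries frame index, box and dt.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_particles}\n")
            fh.write(
                f"frame={f} box=\"{traj.box[0]:.6f} {traj.box[1]:.6f}\" dt={traj.dt:.6f}\n"
            )
            for p in range(traj.n_particles):
                x, y, z = traj.coords[f, p]
                fh.write(
                    f"{traj.species[p]} {traj.leaflet[p]} {traj.role[p]} "
                    f"{int(traj.mol_id[p])} {x:.6f} {y:.6f} {z:.6f}\n"
                )
    write_manifest(path, traj.metadata)
    return path


def read_xyz(path: str | Path) -> BilayerTrajectory:
    frames = []
    species = leaflet = role = mol_id = None
    box = (0.0, 0.0)
    dt = 1.0
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"malformed XYZ atom count at line {i + 1}") from exc
        comment = lines[i + 1]
        for tok in comment.replace('"', "").split():
            if tok.startswith("dt="):
                dt = float(tok[3:])
        if "box=" in comment:
            inner = comment.split('box="', 1)[1].split('"', 1)[0]
            bx, by = inner.split()
            box = (float(bx), float(by))
        sp, lf, rl, mi, coords = [], [], [], [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) != 7:
                raise ValueError(f"malformed XYZ particle record at line {i + 3 + j}")
            sp.append(parts[0])
            lf.append(parts[1])
            rl.append(parts[2])
            mi.append(int(parts[3]))
            coords.append([float(parts[4]), float(parts[5]), float(parts[6])])
        if species is None:
            species, leaflet, role, mol_id = sp, lf, rl, mi
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError("no frames in XYZ file")
    return BilayerTrajectory(
        coords=np.array(frames),
        species=np.array(species),
        leaflet=np.array(leaflet),
        role=np.array(role),
        mol_id=np.array(mol_id),
        box=box,
        dt=dt,
    )


def read_gro(
    path: str | Path,
    species_map: Mapping[str, str],
    role_map: Mapping[str, str] | None = None,
    dt: float = 1.0,
) -> BilayerTrajectory:
    """Minimal single-frame GRO reader.

    ``species_map`` maps residue names to species labels (unknown
    residues raise); ``role_map`` maps atom names to roles (default:
    "P"→phosphate, others become chain sites in file order).  Leaflets
    are assigned by the sign of z relative to the mean phosphate z.
    Coordinates are converted nm → Å.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError("GRO file too short")
    n = int(lines[1].strip())
    box_tokens = lines[2 + n].split()
    box = (float(box_tokens[0]) * 10.0, float(box_tokens[1]) * 10.0)
    species, role, mol_id, coords = [], [], [], []
    chain_counter: dict[int, int] = {}
    for ln in lines[2 : 2 + n]:
        resid = int(ln[0:5])
        resname = ln[5:10].strip()
        atom = ln[10:15].strip()
        x, y, z = (float(ln[20:28]) * 10.0, float(ln[28:36]) * 10.0, float(ln[36:44]) * 10.0)
        if resname not in species_map:
            raise ValueError(f"unknown residue name '{resname}': add it to the species map")
        species.append(species_map[resname])
        if role_map and atom in role_map:
            role.append(role_map[atom])
        elif atom.upper().startswith("P"):
            role.append("phosphate")
        else:
            k = chain_counter.get(resid, 0)
            role.append(f"chain_{k}")
            chain_counter[resid] = k + 1
        mol_id.append(resid)
        coords.append([x, y, z])
    coords = np.array(coords)[None, :, :]
    z = coords[0, :, 2]
    phos = np.array([r == "phosphate" for r in role])
    mid = z[phos].mean() if phos.any() else z.mean()
    leaflet = np.where(z >= mid, "upper", "lower")
    return BilayerTrajectory(
        coords=coords,
        species=np.array(species),
        leaflet=leaflet,
        role=np.array(role),
        mol_id=np.array(mol_id),
        box=box,
        dt=dt,
    )


# ---------------------------------------------------------------------------
# FLIM stacks (TIFF + JSON sidecar)
# ---------------------------------------------------------------------------


def write_flim_stack(stack: FLIMStack, path: str | Path) -> Path:
    import tifffile

    path = Path(path)
    # store channel-first for multi-frame TIFF convention
    tifffile.imwrite(path, np.moveaxis(stack.data, 2, 0).astype(np.float32))
    sidecar = {
        "channel_width_ns": stack.channel_width,
        "irf_counts": stack.irf_counts.tolist(),
        "shape": list(stack.data.shape),
    }
    meta = {
        k: v for k, v in stack.metadata.items() if k not in ("truth_lifetime", "rim_mask")
    }
    sidecar["metadata"] = _to_jsonable(meta)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_flim_stack(path: str | Path) -> FLIMStack:
    import tifffile

    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise ValueError("FLIM stack requires its JSON sidecar next to the TIFF")
    sidecar = json.loads(sidecar_path.read_text())
    data = np.moveaxis(tifffile.imread(path), 0, 2)
    return FLIMStack(
        data=data,
        channel_width=float(sidecar["channel_width_ns"]),
        irf_counts=np.array(sidecar["irf_counts"]),
        metadata=sidecar.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# configuration / pipeline
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict[str, Any]:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def config_hash(cfg: Mapping[str, Any]) -> str:
    blob = json.dumps(_to_jsonable(dict(cfg)), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def metric_table(records: Sequence[Mapping[str, Any]], cfg_hash: str) -> pd.DataFrame:
    """Tidy metric records; every row carries units and the config hash."""
    df = pd.DataFrame.from_records(records)
    for col in ("sample_id", "metric", "value", "units"):
        if col not in df.columns:
            raise ValueError(f"metric records missing '{col}'")
    if df["units"].isna().any() or (df["units"].astype(str) == "").any():
        raise ValueError("every metric must state its units")
    df["provenance"] = f"oxmembrane:{cfg_hash}"
    return df


def run_pipeline(config: Mapping[str, Any] | str | Path, out_dir: str | Path | None = None):
    """Run the demo analysis stages listed in a configuration.

    The configuration is a mapping with ``seed``, optional ``stages``
    (subset of flim/spectra/scattering/bilayer; default all) and
    optional per-stage parameter overrides.  Each stage synthesizes its
    own input with the stage seed, runs the analysis, and contributes
    tidy metric rows.  Stage failures are recorded and do not stop the
    other stages.  Returns (metric DataFrame, errors dict).
    """
    from . import bilayer as bl
    from . import flim as fl
    from . import scattering as sc
    from . import spectra as spc
    from . import synthetic_data as syn

    if isinstance(config, (str, Path)):
        config = load_config(config)
    cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", ["flim", "spectra", "scattering", "bilayer"])
    h = config_hash(cfg)
    records: list[dict[str, Any]] = []
    errors: dict[str, str] = {}

    if "flim" in stages:
        try:
            spec = syn.DecaySimSpec(
                lifetimes=[float(cfg.get("lifetime_ns", 2.1))],
                amplitudes=[1.0],
                peak_counts=int(cfg.get("peak_counts", 10_000)),
                seed=seed,
            )
            trace = syn.gen_decay(spec)
            fit = fl.fit_decay(trace, n_components=1)
            tau = fl.select_reported_lifetime(fit, "mono")
            eta = fl.lifetime_to_viscosity(tau, fl.default_calibration())
            records += [
                dict(sample_id="synthetic_decay", metric="lifetime", value=tau, units="ns"),
                dict(sample_id="synthetic_decay", metric="microviscosity", value=eta, units="cP"),
            ]
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            errors["flim"] = f"{type(exc).__name__}: {exc}"

    if "spectra" in stages:
        try:
            spec = syn.SpectrumSimSpec(
                components=[(425.0, 45.0, 1.3, 1.0), (460.0, 50.0, 1.3, 0.8), (495.0, 55.0, 1.3, 0.6)],
                noise_sd=float(cfg.get("spectrum_noise_sd", 0.01)),
                seed=seed + 1,
            )
            spectrum = syn.gen_spectrum(spec)
            gp = spc.compute_gp(spectrum)
            dec = spc.decompose_lognormal3(spectrum, seed=seed + 1)
            records.append(dict(sample_id="synthetic_spectrum", metric="gp", value=gp.gp, units="1"))
            for k, (c, _w, _r, frac) in enumerate(dec.components):
                records.append(
                    dict(sample_id="synthetic_spectrum", metric=f"band{k}_center", value=c, units="nm")
                )
                records.append(
                    dict(sample_id="synthetic_spectrum", metric=f"band{k}_area_fraction", value=frac, units="1")
                )
        except Exception as exc:  # noqa: BLE001
            errors["spectra"] = f"{type(exc).__name__}: {exc}"

    if "scattering" in stages:
        try:
            spec = syn.ScatterSimSpec(
                d_spacing=float(cfg.get("d_spacing", 62.8)),
                n_orders=3,
                noise_sd=float(cfg.get("profile_noise_sd", 0.01)),
                seed=seed + 2,
            )
            profile = syn.gen_scatter(spec)
            lam = sc.find_bragg_peaks(profile)
            waxs = sc.fit_waxs(profile)
            records += [
                dict(sample_id="synthetic_profile", metric="d_spacing", value=lam.d_spacing, units="Å"),
                dict(sample_id="synthetic_profile", metric="waxs_chain_spacing", value=waxs.chain_spacing, units="Å"),
            ]
        except Exception as exc:  # noqa: BLE001
            errors["scattering"] = f"{type(exc).__name__}: {exc}"

    if "bilayer" in stages:
        try:
            spec = syn.BilayerSimSpec(
                n_per_leaflet=int(cfg.get("n_per_leaflet", 100)),
                box_lengths=(82.0, 82.0),
                species_fractions={"POPC": 0.5, "POPC-OOH": 0.5},
                n_frames=int(cfg.get("n_frames", 100)),
                seed=seed + 3,
            )
            traj = syn.gen_bilayer_traj(spec)
            thick, thick_se = bl.bilayer_thickness(traj)
            enr = bl.enrichment(traj, seed=seed + 3)
            diff = bl.msd_diffusion(traj, species="POPC")
            snork = bl.snorkelling_fraction(traj)
            records += [
                dict(sample_id="synthetic_bilayer", metric="thickness", value=thick, units="Å", se=thick_se),
                dict(sample_id="synthetic_bilayer", metric="E_selfOOH", value=enr[("POPC-OOH", "POPC-OOH")], units="1"),
                dict(sample_id="synthetic_bilayer", metric="D_POPC", value=diff.D, units="Å²/ns", se=diff.se),
                dict(sample_id="synthetic_bilayer", metric="snorkel_fraction", value=snork.fraction, units="1"),
            ]
        except Exception as exc:  # noqa: BLE001
            errors["bilayer"] = f"{type(exc).__name__}: {exc}"

    table = metric_table(records, h) if records else pd.DataFrame()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "metrics.tsv", sep="\t", index=False)
        manifest = {
            "config": _to_jsonable(cfg),
            "config_hash": h,
            "seed": seed,
            "stages": list(stages),
            "errors": errors,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return table, errors
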