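"""Text file formats and run configuration.

Cross-spectra travel as delimited text with one row per (frequency, channel
pair): columns ``frequency_hz, channel_i, channel_j, real, imag`` for the
upper triangle (0-based channel indices, i <= j), with ``#``-prefixed header
lines carrying channel labels.  Depth-LFP traces, design matrices and scored
model tables are plain TSV.  Run configurations are YAML with a fixed
schema; unknown keys are rejected and all defaults are materialised into the
resolved configuration that every CLI run saves next to its outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .types import DepthLFP, GaussianDensity, SpectralData

__all__ = [
    "read_spectra", "write_spectra",
    "read_depth_lfp", "write_depth_lfp",
    "read_design", "write_design",
    "write_density", "read_density",
    "write_scored_models",
    "default_config", "load_config", "resolve_config", "save_config",
]


# ---------------------------------------------------------------------------
# Cross-spectra
# ---------------------------------------------------------------------------

def write_spectra(data: SpectralData, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# spectraldcm cross-spectral density\n")
        fh.write(f"# channels: {','.join(data.channel_names)}\n")
        fh.write("# units: frequency_hz, csd a.u.\n")
        fh.write("frequency_hz,channel_i,channel_j,real,imag\n")
        for fi, f in enumerate(data.freqs):
            for i in range(data.n_channels):
                for j in range(i, data.n_channels):
                    z = data.csd[fi, i, j]
                    fh.write(f"{f:.10g},{i},{j},{z.real:.12g},{z.imag:.12g}\n")


def read_spectra(path) -> SpectralData:
    """Parse and validate a cross-spectra file.

    Errors name the offending (frequency, i, j) for duplicate or missing
    pairs, and the line number for non-numeric fields; auto-spectrum rows
    must have zero imaginary part.  The lower triangle is filled by
    conjugation.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    channel_names = None
    rows = {}
    freqs_order = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("channels:"):
                    channel_names = tuple(
                        s.strip() for s in body[len("channels:"):].split(",") if s.strip()
                    )
                continue
            if line.startswith("frequency_hz"):
                continue
            fields = line.split(",")
            if len(fields) != 5:
                raise ValidationError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
            try:
                f = float(fields[0])
                i, j = int(fields[1]), int(fields[2])
                re, im = float(fields[3]), float(fields[4])
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: non-numeric field") from None
            if i > j:
                raise ValidationError(
                    f"{path}:{lineno}: lower-triangle pair (freq={f:g}, i={i}, j={j}); "
                    "only i <= j rows are allowed"
                )
            if i == j and im != 0.0:
                raise ValidationError(
                    f"{path}:{lineno}: auto-spectrum (freq={f:g}, i={i}) has nonzero "
                    "imaginary part"
                )
            key = (f, i, j)
            if key in rows:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate pair (freq={f:g}, i={i}, j={j})"
                )
            rows[key] = re + 1j * im
            if f not in freqs_order:
                freqs_order.append(f)
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    nc = max(j for (_, _, j) in rows) + 1
    freqs = np.array(sorted(freqs_order))
    csd = np.zeros((freqs.size, nc, nc), dtype=complex)
    for fi, f in enumerate(freqs):
        for i in range(nc):
            for j in range(i, nc):
                if (f, i, j) not in rows:
                    raise ValidationError(
                        f"{path}: missing pair (freq={f:g}, i={i}, j={j})"
                    )
                csd[fi, i, j] = rows[(f, i, j)]
                csd[fi, j, i] = np.conj(rows[(f, i, j)])
    if channel_names is not None and len(channel_names) != nc:
        raise ValidationError(
            f"{path}: header lists {len(channel_names)} channels but data has {nc}"
        )
    return SpectralData(freqs, csd, channel_names)


# ---------------------------------------------------------------------------
# Depth LFP
# ---------------------------------------------------------------------------

def write_depth_lfp(lfp: DepthLFP, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# contact spacing (um): {lfp.spacing:.10g}\n")
        fh.write("# columns: time_ms then contacts ordered superficial -> deep\n")
        cols = "\t".join(["time_ms"] + [f"c{i}" for i in range(lfp.depths.size)])
        fh.write(cols + "\n")
        for ti, t in enumerate(lfp.times):
            vals = "\t".join(f"{x:.10g}" for x in lfp.v[:, ti])
            fh.write(f"{t:.10g}\t{vals}\n")


def read_depth_lfp(path) -> DepthLFP:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    spacing = None
    with path.open() as fh:
        for line in fh:
            if line.startswith("#") and "spacing" in line:
                try:
                    spacing = float(line.split(":")[-1])
                except ValueError:
                    raise ValidationError(f"{path}: malformed spacing header") from None
    if spacing is None:
        raise ValidationError(f"{path}: missing contact-spacing header comment")
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 4:
        raise ValidationError(f"{path}: need a time column and >= 3 contacts")
    times = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1:].to_numpy(dtype=float).T
    depths = np.arange(v.shape[0]) * spacing
    return DepthLFP(times=times, depths=depths, v=v)


# ---------------------------------------------------------------------------
# Design matrices and densities
# ---------------------------------------------------------------------------

def write_design(X, covariate_names, path) -> None:
    pd.DataFrame(np.atleast_2d(np.asarray(X, dtype=float)),
                 columns=list(covariate_names)).to_csv(path, sep="\t", index=False)


def read_design(path):
    """Read a subjects × covariates design matrix (TSV, header row)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValidationError(f"{path}: empty design matrix")
    try:
        X = df.to_numpy(dtype=float)
    except ValueError:
        raise ValidationError(f"{path}: non-numeric entries in design matrix") from None
    return X, tuple(df.columns)


def write_density(density: GaussianDensity, path) -> None:
    """Serialise a Gaussian density (names, mean, covariance) as JSON."""
    payload = {
        "names": list(density.names),
        "mean": density.mean.tolist(),
        "cov": density.cov.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_density(path) -> GaussianDensity:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        payload = json.loads(path.read_text())
        return GaussianDensity(tuple(payload["names"]),
                               np.asarray(payload["mean"], dtype=float),
                               np.asarray(payload["cov"], dtype=float))
    except (KeyError, json.JSONDecodeError) as exc:
        raise ValidationError(f"{path}: malformed density file ({exc})") from None


def _density_payload(d: GaussianDensity) -> dict:
    return {"names": list(d.names), "mean": d.mean.tolist(), "cov": d.cov.tolist()}


def write_inversion_result(result, path) -> None:
    """Serialise an InversionResult (densities, free energy, trajectory) as JSON."""
    payload = {
        "posterior": _density_payload(result.posterior),
        "prior": _density_payload(result.prior),
        "hyper_posterior": _density_payload(result.hyper_posterior),
        "free_energy": result.free_energy,
        "trajectory": np.asarray(result.trajectory).tolist(),
        "n_data": int(result.n_data),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_inversion_result(path):
    from .types import InversionResult

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        p = json.loads(path.read_text())
        dens = lambda d: GaussianDensity(tuple(d["names"]),
                                         np.asarray(d["mean"], dtype=float),
                                         np.asarray(d["cov"], dtype=float))
        return InversionResult(
            posterior=dens(p["posterior"]),
            hyper_posterior=dens(p["hyper_posterior"]),
            free_energy=float(p["free_energy"]),
            trajectory=np.asarray(p["trajectory"], dtype=float),
            prediction=None,
            prior=dens(p["prior"]),
            n_data=int(p["n_data"]),
        )
    except (KeyError, json.JSONDecodeError) as exc:
        raise ValidationError(f"{path}: malformed inversion file ({exc})") from None


def write_scored_models(scored, path) -> None:
    """Scored reduced models as TSV: mask, free energy, posterior probability."""
    with Path(path).open("w") as fh:
        fh.write("mask\tfree_energy\tprobability\n")
        for s in scored:
            mask = "+".join(s.mask) if s.mask else "(none)"
            fh.write(f"{mask}\t{s.free_energy:.6f}\t{s.probability:.6g}\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_SCHEMA = {
    "model": {
        "kind": "mass",              # mass | field
        "params": {},                # overrides of the model dataclass fields
        "free": ["a14", "a32"],      # free (log-scale) parameter names
        "prior_var": 1.0 / 16.0,
        "freqs": {"start": 4.0, "stop": 100.0, "step": 1.0},
    },
    "inversion": {
        "max_iter": 64,
        "tol_nats": 0.01,
        "lm_init": 0.125,
        "fd_step": 1e-4,
        "estimate_noise": True,
        "lambda_init": 0.0,
    },
    "peb": {
        "design": None,              # path to a design TSV
        "covariates": None,          # optional covariate-name subset
        "re_base_precision": 16.0,
        "gamma_prior_var": 16.0,
    },
    "simulate": {
        "noise_sd": 0.5,
        "n_subjects": 16,
        "re_sd": 0.1,
        "cross_gain": 1.0,
    },
    "seed": 0,
    "output_dir": ".",
}


def default_config() -> dict:
    import copy

    return copy.deepcopy(_CONFIG_SCHEMA)


def _merge_checked(schema, user, path=""):
    if not isinstance(user, dict):
        raise ValidationError(f"config section {path or '<root>'} must be a mapping")
    out = {}
    for key, default in schema.items():
        if key in user and isinstance(default, dict) and key not in ("params", "freqs"):
            out[key] = _merge_checked(default, user[key], f"{path}{key}.")
        elif key in user:
            out[key] = user[key]
        else:
            out[key] = default
    unknown = set(user) - set(schema)
    if unknown:
        raise ValidationError(f"unknown config keys under {path or '<root>'}: {sorted(unknown)}")
    return out


def resolve_config(user: dict | None) -> dict:
    """Merge a user configuration over the defaults, rejecting unknown keys."""
    import copy

    return _merge_checked(copy.deepcopy(_CONFIG_SCHEMA), user or {})


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such config file: {path}")
    try:
        user = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ValidationError(f"{path}: invalid YAML ({exc})") from None
    return resolve_config(user)


def save_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def config_freqs(config: dict) -> np.ndarray:
    fr = config["model"]["freqs"]
    freqs = np.arange(float(fr["start"]), float(fr["stop"]) + 1e-9, float(fr["step"]))
    if freqs.size == 0 or freqs[0] <= 0:
        raise ValidationError("config model.freqs must define a positive grid")
    return freqs
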