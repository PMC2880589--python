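"""Run configuration: parsing, validation, serialization, fixtures.

A run is described by one flat YAML/JSON mapping.  Unknown keys are
rejected by name, defaults are filled from :class:`~gcmature.core.ModelParams`,
and every parsed config carries a content hash that output writers stamp
into their provenance headers.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import ModelParams
from .numeric import TERMINATION_MODES
from .spectrum import default_spectrum, write_spectrum_tsv

__all__ = ["RunConfig", "parse_config", "serialize_config", "make_fixtures"]

_RANGES = {
    "p": (0.0, 0.999999),
    "ka_in_ratio": (1e-6, 1e3),
    "b": (0.0, 100.0),
    "h": (1e-6, 10.0),
    "kT": (1e-6, 10.0),
    "N0": (1.0, 1e12),
    "t_max": (0.0, 1e4),
    "divisions_per_day": (1, 64),
    "f_silent": (0.0, 1.0),
    "f_lethal": (0.0, 1.0),
    "f_affinity": (0.0, 1.0),
    "replicates": (1, 1_000_000),
    "n_bins": (2, 10_000),
    "seed": (0, 2**31 - 1),
}


@dataclass
class RunConfig:
    """Validated flat configuration for any subcommand."""

    p: float = 0.5
    divisions_per_day: int = 4
    kT: float = 0.59
    b: float = 0.7
    h: float = 0.5
    f_silent: float = 0.5
    f_lethal: float = 0.3
    f_affinity: float = 0.2
    ka_in_ratio: float | None = None
    x_in_offset: float | None = None
    N0: float = 1e5
    t_max: float = 100.0
    spectrum: str = "default"
    termination: str = "fixed_window_14d"
    p_grid: list[float] | None = None
    ka_in_grid: list[float] | None = None
    b_grid: list[float] | None = None
    replicates: int = 100
    n_bins: int = 20
    seed: int = 0
    out: str | None = None

    def __post_init__(self) -> None:
        if self.ka_in_ratio is None and self.x_in_offset is None:
            self.ka_in_ratio = 0.18
        if self.x_in_offset is None:
            self.x_in_offset = -self.kT * math.log(self.ka_in_ratio)
        elif self.ka_in_ratio is None:
            self.ka_in_ratio = math.exp(-self.x_in_offset / self.kT)
        if self.termination not in TERMINATION_MODES:
            raise ValueError(f"unknown termination mode {self.termination!r}")

    def model_params(self) -> ModelParams:
        return ModelParams(
            divisions_per_day=self.divisions_per_day,
            kT=self.kT,
            b=self.b,
            h=self.h,
            p_mutated_daughter=self.p,
            f_silent=self.f_silent,
            f_lethal=self.f_lethal,
            f_affinity=self.f_affinity,
            X_star_offset_in=self.x_in_offset,
            N0=self.N0,
            t_max=self.t_max,
        )

    def load_spectrum(self):
        if self.spectrum == "default":
            return default_spectrum(self.kT)
        path = Path(self.spectrum)
        if not path.exists():
            raise FileNotFoundError(f"spectrum file not found: {path}")
        if path.suffix == ".tsv" and "offset" not in path.read_text().splitlines()[0]:
            from .spectrum import from_ddg_table, read_ddg_tsv

            return from_ddg_table(read_ddg_tsv(path), self.h)
        from .spectrum import read_spectrum_tsv

        return read_spectrum_tsv(path)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance_lines(self) -> list[str]:
        from . import __version__

        return [f"gcmature {__version__}", f"config_hash {self.config_hash()}"]


def _validate(raw: dict) -> None:
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, (lo, hi) in _RANGES.items():
        if key in raw and raw[key] is not None:
            v = raw[key]
            if not (lo <= v <= hi):
                raise ValueError(f"config key {key!r} out of range [{lo}, {hi}]: {v}")


def parse_config(source) -> RunConfig:
    """Parse a config from a path, YAML/JSON text, or mapping."""
    if isinstance(source, dict):
        raw = dict(source)
    else:
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat key/value mapping")
    _validate(raw)
    return RunConfig(**raw)


def serialize_config(cfg: RunConfig) -> str:
    """YAML dump that round-trips through :func:`parse_config`."""
    d = {k: v for k, v in asdict(cfg).items() if v is not None}
    return yaml.safe_dump(d, sort_keys=True)


_REFERENCE_CONFIGS = {
    # pooled spleen in the fast-migration limit: improvement landscape
    "pooled_spleen.yaml": dict(
        N0=1e5, termination="fixed_window_14d", b=0.7, p=0.5, ka_in_ratio=0.18
    ),
    # single isolated germinal center, recovery-based termination
    "isolated_gc.yaml": dict(
        N0=3000.0, termination="recovery_unbounded", b=0.7, p=0.6, ka_in_ratio=0.25
    ),
    # all-or-none reference run
    "allornone.yaml": dict(
        N0=3000.0, termination="recovery_unbounded", b=0.7, p=0.5, ka_in_ratio=0.5
    ),
}


def make_fixtures(seed: int, outdir) -> dict[str, Path]:
    """Write the reference fixture bundle.

    Produces a 500-row synthetic per-mutation ddG table sampled from the
    packaged default spectrum (bin centers jittered uniformly within
    +-0.2 kcal/mol so re-binning recovers the spectrum exactly in
    expectation) and the three reference run configs.  Byte-identical for
    identical seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    spec = default_spectrum()
    n = 500
    draws = rng.choice(len(spec.offsets), size=n, p=np.asarray(spec.weights))
    jitter = rng.uniform(-0.2, 0.2, size=n)
    values = np.asarray(spec.offsets)[draws] + jitter
    written: dict[str, Path] = {}

    ddg_path = outdir / "synthetic_ddg.tsv"
    with open(ddg_path, "w") as fh:
        fh.write("# synthetic per-mutation ddG values sampled from the packaged default spectrum\n")
        fh.write(f"# seed {seed}\n")
        fh.write("ddG_kcal_per_mol\n")
        for v in values:
            fh.write(f"{v:.6f}\n")
    written["synthetic_ddg.tsv"] = ddg_path

    for name, overrides in _REFERENCE_CONFIGS.items():
        cfg = RunConfig(seed=seed, **overrides)
        path = outdir / name
        path.write_text(serialize_config(cfg))
        written[name] = path

    spath = outdir / "default_spectrum.tsv"
    write_spectrum_tsv(spec, spath, header_lines=["packaged default mutation-effect spectrum"])
    written["default_spectrum.tsv"] = spath
    return written
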