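"""Flat key-value configuration holding every tunable threshold of the pipeline.

Keys are dotted ``section.key`` names; every numeric rule parameter used anywhere
in the package has a documented default here so that it is visible and can be
overridden from a plain-text config file (``section.key = value`` lines, ``#``
comments allowed).  Unknown keys are rejected and values are coerced to the type
of the default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

__all__ = ["Config", "DEFAULTS", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown keys or values that cannot be coerced."""


#: Default value (and implicitly the type) of every tunable parameter.
DEFAULTS: dict[str, Any] = {
    # --- cysteine framework search -----------------------------------------
    # A-chain motif C-C-x(a)-C-x(b)-C; spacings generalize the human insulin
    # spacings 3 / 8; the B-chain cysteines are 12 apart in insulin.
    "framework.a_gap_min": 2,
    "framework.a_gap_max": 6,
    "framework.b_gap_min": 6,
    "framework.b_gap_max": 14,
    "framework.bpair_min": 8,
    "framework.bpair_max": 16,
    "framework.c_span_min": 5,
    "framework.c_span_max": 80,
    # modal spacings scored by the search
    "framework.a_gap_mode": 3,
    "framework.b_gap_mode": 8,
    "framework.bpair_mode": 12,
    # --- cleavage prediction ------------------------------------------------
    "cleavage.signal_min": 15,
    "cleavage.signal_max": 35,
    "cleavage.signal_hydro_min": 1.5,
    "cleavage.bulky_p1prime": "WFYILV",
    "cleavage.small_residues": "AGSCT",
    "cleavage.disulfide_window": 3,
    "cleavage.enable_kr": True,
    "cleavage.enable_rr": False,
    "cleavage.enable_kk": False,
    "cleavage.enable_rk": False,
    "cleavage.enable_monobasic": False,
    # --- domain segmentation --------------------------------------------------
    "domains.b_lead": 8,    # B-chain residues allowed upstream of CB1
    "domains.f_min": 15,    # minimum length for a distinct F domain
    # --- classification -------------------------------------------------------
    "classify.tail_min": 25,
    "classify.charged_min": 0.3,
    "classify.f_identity_min": 0.4,
    # a single unpaired cysteine forms no bridge, so it does not count against
    # the six-cysteine (GSS) framework
    "classify.gss_max_extra_cys": 1,
    "classify.b_max": 30,   # B domains longer than this flag an anomaly
    "classify.octinsulin_extra_domains": "B,D",
    "classify.multinsulin_extra_domain": "C",
    # --- gene structure -------------------------------------------------------
    "genes.igf_terminal_frac": 0.25,  # "near the end" = last quarter of the CDS
    # --- synteny ---------------------------------------------------------------
    "synteny.max_gap": 1_000_000,
    # --- similarity trees ------------------------------------------------------
    "tree.gap_open": 11,
    "tree.gap_extend": 1,
    "tree.correction": "p",        # or "poisson"
    "tree.poisson_cap": 5.0,
    "tree.region": "core",         # B+A core (default) or "mature"
    # --- receptor annotation ---------------------------------------------------
    "receptor.kd_window": 19,
    "receptor.kd_threshold": 1.6,
    "receptor.tm_min_run": 8,
    "receptor.tm_merge_gap": 3,
    "receptor.lrr_collapse": 20,
    "receptor.ldla_follow": 12,
    "receptor.ldla_acid_window": 8,
    "receptor.ldla_acid_min": 3,
}


def _coerce(key: str, raw: str, default: Any) -> Any:
    if isinstance(default, bool):
        low = raw.strip().lower()
        if low in {"true", "1", "yes", "on"}:
            return True
        if low in {"false", "0", "no", "off"}:
            return False
        raise ConfigError(f"{key}: cannot parse boolean from {raw!r}")
    try:
        if isinstance(default, int):
            return int(raw)
        if isinstance(default, float):
            return float(raw)
    except ValueError as exc:
        raise ConfigError(f"{key}: cannot parse {raw!r}") from exc
    return raw.strip()


class Config(Mapping[str, Any]):
    """Immutable view over :data:`DEFAULTS` with optional overrides."""

    def __init__(self, overrides: Mapping[str, Any] | None = None) -> None:
        values = dict(DEFAULTS)
        for key, val in (overrides or {}).items():
            if key not in DEFAULTS:
                raise ConfigError(f"unknown config key: {key}")
            default = DEFAULTS[key]
            if isinstance(val, str) and not isinstance(default, str):
                val = _coerce(key, val, default)
            if isinstance(default, bool) and not isinstance(val, bool):
                raise ConfigError(f"{key}: expected boolean, got {val!r}")
            if isinstance(default, int) and not isinstance(default, bool):
                if isinstance(val, bool) or not isinstance(val, (int, float)):
                    raise ConfigError(f"{key}: expected number, got {val!r}")
                val = int(val)
            if isinstance(default, float) and isinstance(val, (int, float)):
                val = float(val)
            values[key] = val
        self._values = values

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        overrides: dict[str, Any] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'section.key = value'")
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in DEFAULTS:
                raise ConfigError(f"{path}:{lineno}: unknown config key: {key}")
            overrides[key] = _coerce(key, raw.strip(), DEFAULTS[key])
        return cls(overrides)

    def __getitem__(self, key: str) -> Any:
        return self._values[key]

    def __iter__(self):
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def replace(self, **dotted: Any) -> "Config":
        """Return a new Config with keyword overrides (dots written as ``__``)."""
        overrides = {k.replace("__", "."): v for k, v in dotted.items()}
        merged = {k: v for k, v in self._values.items() if DEFAULTS[k] != v}
        merged.update(overrides)
        return Config(merged)
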