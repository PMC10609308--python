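"""Run configuration: defaults, YAML config file, command-line overrides.

Every tunable of the pipeline lives in one of the stage dataclasses
(AlignScoring, DesignConstraints, SpecificityRules, SeparabilityRule,
ThermoConditions) plus a few scalar knobs.  :class:`RunConfig` merges the
three layers (defaults < config file < flags) and remembers where each
value came from, so run manifests can echo full provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .align import AlignScoring
from .multiplex import SeparabilityRule
from .primer_design import DesignConstraints, SpecificityRules
from .thermo import ThermoConditions

__all__ = ["RunConfig", "write_manifest"]

_SECTIONS = {
    "scoring": AlignScoring,
    "constraints": DesignConstraints,
    "specificity": SpecificityRules,
    "separability": SeparabilityRule,
    "thermo": ThermoConditions,
}

_SCALAR_DEFAULTS = {
    "k": 21,
    "min_len": 1000,
    "merge_gap": 100,
    "max_candidates": 25,
    "n_sets": 3,
}


@dataclass
class RunConfig:
    scoring: AlignScoring
    constraints: DesignConstraints
    specificity: SpecificityRules
    separability: SeparabilityRule
    thermo: ThermoConditions
    scalars: dict[str, Any]
    provenance: dict[str, str]

    @classmethod
    def load(
        cls,
        config_path: str | Path | None = None,
        overrides: dict[str, Any] | None = None,
    ) -> "RunConfig":
        """Merge defaults, an optional YAML file, and flag overrides.

        ``overrides`` maps scalar names (``k`` ...) or dotted section fields
        (``constraints.product_max`` ...) to values; None values are ignored.
        """
        file_cfg: dict[str, Any] = {}
        if config_path is not None:
            file_cfg = yaml.safe_load(Path(config_path).read_text()) or {}
        overrides = {k: v for k, v in (overrides or {}).items() if v is not None}
        provenance: dict[str, str] = {}
        sections: dict[str, Any] = {}
        for name, klass in _SECTIONS.items():
            values = {}
            for fld in dataclasses.fields(klass):
                key = f"{name}.{fld.name}"
                if key in overrides:
                    values[fld.name] = overrides[key]
                    provenance[key] = "flag"
                elif fld.name in file_cfg.get(name, {}):
                    values[fld.name] = file_cfg[name][fld.name]
                    provenance[key] = "config"
                else:
                    provenance[key] = "default"
            sections[name] = klass(**values)
        scalars = {}
        for key, default in _SCALAR_DEFAULTS.items():
            if key in overrides:
                scalars[key] = overrides[key]
                provenance[key] = "flag"
            elif key in file_cfg:
                scalars[key] = file_cfg[key]
                provenance[key] = "config"
            else:
                scalars[key] = default
                provenance[key] = "default"
        return cls(
            scoring=sections["scoring"],
            constraints=sections["constraints"],
            specificity=sections["specificity"],
            separability=sections["separability"],
            thermo=sections["thermo"],
            scalars=scalars,
            provenance=provenance,
        )

    def as_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            name: dataclasses.asdict(getattr(self, name)) for name in _SECTIONS
        }
        out.update(self.scalars)
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    stage: str,
    inputs: list[str | Path],
    config: RunConfig,
    seed: int | None = None,
    extra: dict[str, Any] | None = None,
) -> None:
    """Write a JSON run manifest sufficient to reproduce the outputs."""
    from . import __version__

    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "inputs": [
            {"path": str(p), "sha256": _sha256(Path(p))} for p in inputs
        ],
        "config": config.as_dict(),
        "provenance": config.provenance,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2))
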