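"""Load PBPK parameter sets from TOML, with provenance tracking.

The schema mirrors the shipped ``data/defaults.toml``: sections
``[compartments.<name>]`` (one per tissue), ``[metabolism]``,
``[physiology]`` and ``[constants]``. Every numeric key may carry a sibling
``<key>_source`` string; these are collected into
:attr:`PBPKParameters.provenance` so a run log can show where each number
came from. The shipped defaults are illustrative placeholders, not vetted
literature values.
"""

from __future__ import annotations

import tomllib
from importlib import resources
from pathlib import Path
from typing import Any

from .errors import ConfigError
from .pbpk_core import (
    CompartmentName,
    CompartmentParams,
    MetabolismParams,
    PBPKParameters,
    Physiology,
)

_SOURCE_SUFFIX = "_source"


def _split_sources(section: dict[str, Any], prefix: str, provenance: dict[str, str]) -> dict[str, Any]:
    """Separate numeric keys from their `<key>_source` provenance strings."""
    values: dict[str, Any] = {}
    for key, val in section.items():
        if key.endswith(_SOURCE_SUFFIX):
            provenance[f"{prefix}{key[: -len(_SOURCE_SUFFIX)]}"] = str(val)
        else:
            values[key] = val
    return values


def _load_toml(path: str | Path | None) -> dict[str, Any]:
    if path is None:
        ref = resources.files("benzrisk").joinpath("data/defaults.toml")
        return tomllib.loads(ref.read_text(encoding="utf-8"))
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def load_parameters(path: str | Path | None = None) -> tuple[PBPKParameters, Physiology]:
    """Read a parameter TOML (or the packaged defaults) into validated objects."""
    raw = _load_toml(path)
    provenance: dict[str, str] = {}

    comp_section = raw.get("compartments")
    if not isinstance(comp_section, dict):
        raise ConfigError("missing [compartments.<name>] sections")
    compartments = []
    for name in CompartmentName:
        if name.value not in comp_section:
            raise ConfigError(f"missing [compartments.{name.value}] section")
        fields = _split_sources(
            comp_section[name.value], f"compartments.{name.value}.", provenance
        )
        try:
            compartments.append(CompartmentParams(name=name, **fields))
        except TypeError as exc:
            raise ConfigError(f"[compartments.{name.value}]: {exc}") from exc

    met_fields = _split_sources(raw.get("metabolism", {}), "metabolism.", provenance)
    try:
        metabolism = MetabolismParams(**met_fields)
    except TypeError as exc:
        raise ConfigError(f"[metabolism]: {exc}") from exc

    phys_fields = _split_sources(raw.get("physiology", {}), "physiology.", provenance)
    try:
        physiology = Physiology(**phys_fields)
    except TypeError as exc:
        raise ConfigError(f"[physiology]: {exc}") from exc

    # [constants] entries are fixed chemistry; recorded for provenance only.
    _split_sources(raw.get("constants", {}), "constants.", provenance)

    params = PBPKParameters(
        compartments=tuple(compartments),
        metabolism=metabolism,
        provenance=provenance,
    )
    return params, physiology


def default_parameters() -> tuple[PBPKParameters, Physiology]:
    """The packaged illustrative parameter set and reference-child physiology."""
    return load_parameters(None)
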