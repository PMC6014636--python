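"""Read and write species thermal-parameter files.

Plain INI-style text, one block per response::

    [species]
    name = ...
    stages = egg, N1, N2, N3, N4, N5
    sex_ratio = 0.5
    rm_floor = -0.02

    [development_rate egg]
    family = briere1
    a = 0.00034209
    ...

    [fecundity]
    family = gaussian
    ...

Floats are written with ``repr`` so a write → read round trip is lossless.
"""

from __future__ import annotations

import configparser
from pathlib import Path

from .families import ConfigurationError
from .species_models import StageModelSet, TemperatureResponse

__all__ = ["read_species_file", "write_species_file"]


def _parser() -> configparser.ConfigParser:
    cp = configparser.ConfigParser(interpolation=None)
    cp.optionxform = str  # keep parameter-name case
    return cp


def write_species_file(models: StageModelSet, path) -> None:
    cp = _parser()
    cp["species"] = {
        "name": models.name,
        "stages": ", ".join(models.stages),
        "sex_ratio": repr(models.sex_ratio),
        "rm_floor": repr(models.rm_floor),
    }

    def add(section: str, resp: TemperatureResponse) -> None:
        cp[section] = {"family": resp.family}
        for k, v in resp.params.items():
            cp[section][k] = repr(float(v))

    for st in models.stages:
        add(f"development_rate {st}", models.development[st])
        add(f"immature_mortality {st}", models.mortality[st])
    add("fecundity", models.fecundity)
    add("senescence_rate", models.senescence)
    with open(path, "w") as fh:
        cp.write(fh)


def read_species_file(path) -> StageModelSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cp = _parser()
    cp.read(path)
    if "species" not in cp:
        raise ConfigurationError(f"{path}: missing [species] section")
    head = cp["species"]
    stages = tuple(s.strip() for s in head["stages"].split(",") if s.strip())

    def load(section: str, kind: str, stage=None) -> TemperatureResponse:
        if section not in cp:
            raise ConfigurationError(f"{path}: missing [{section}] section")
        block = dict(cp[section])
        family = block.pop("family", None)
        if family is None:
            raise ConfigurationError(f"{path}: [{section}] lacks a family name")
        params = {k: float(v) for k, v in block.items()}
        return TemperatureResponse(kind=kind, family=family, params=params, stage=stage)

    return StageModelSet(
        stages=stages,
        development={st: load(f"development_rate {st}", "development_rate", st) for st in stages},
        mortality={st: load(f"immature_mortality {st}", "immature_mortality", st) for st in stages},
        fecundity=load("fecundity", "fecundity"),
        senescence=load("senescence_rate", "senescence_rate"),
        sex_ratio=float(head.get("sex_ratio", "0.5")),
        rm_floor=float(head.get("rm_floor", "-0.02")),
        name=head.get("name", "unnamed"),
    )
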