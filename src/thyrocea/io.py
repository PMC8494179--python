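"""Configuration reading/writing, result export, and run manifests.

The model specification travels as a schema-versioned YAML document; life
tables as two-column CSV (age, q); results as plain CSV tables; the run
manifest as JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .model import (
    ALL_PARAMS,
    COST_PARAMS,
    TRANSITION_PARAMS,
    UTILITY_PARAMS,
    AnalysisSettings,
    Calibration,
    ConfigError,
    CostSet,
    LifeTable,
    ModelSpec,
    ParameterDistribution,
    StrategyTransitions,
    TransitionParameters,
    UtilitySet,
    validate_model,
)
from . import scenarios

__all__ = [
    "SCHEMA_VERSION",
    "load_spec",
    "save_spec",
    "spec_from_dict",
    "spec_to_dict",
    "default_model",
    "read_life_table",
    "write_life_table",
    "RunManifest",
]

SCHEMA_VERSION = 1

_TOP_KEYS = {"schema_version", "settings", "calibration", "life_table", "parameters"}
_SETTINGS_KEYS = set(AnalysisSettings.__dataclass_fields__)
_CALIBRATION_KEYS = set(Calibration.__dataclass_fields__)
_PARAM_KEYS = {"base", "low", "high", "family", "shape_a", "shape_b"}
_LIFE_TABLE_KEYS = {"kind", "life_expectancy", "max_age", "path"}


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {where}; "
            f"allowed: {sorted(allowed)}")


def _life_table_from_dict(d: dict, base_dir: Path | None) -> LifeTable:
    _check_keys(d, _LIFE_TABLE_KEYS, "life_table")
    kind = d.get("kind", "synthetic")
    if kind == "none":
        # no background mortality within the model horizon
        return scenarios.constant_mortality_table(0.0, int(d.get("max_age", 200)))
    if kind == "synthetic":
        return scenarios.synthetic_life_table(
            float(d.get("life_expectancy", 80.0)), int(d.get("max_age", 110)))
    if kind == "csv":
        path = Path(d["path"])
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        return read_life_table(path)
    raise ConfigError(f"unknown life_table kind {kind!r}")


def spec_from_dict(doc: dict, base_dir: Path | None = None) -> ModelSpec:
    """Build a validated :class:`ModelSpec` from a parsed config document."""
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    _check_keys(doc, _TOP_KEYS, "config")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ConfigError(
            f"schema_version {version!r} unsupported (expected {SCHEMA_VERSION})")

    settings_doc = doc.get("settings", {})
    _check_keys(settings_doc, _SETTINGS_KEYS, "settings")
    settings = AnalysisSettings(**settings_doc)

    calib_doc = doc.get("calibration", {})
    _check_keys(calib_doc, _CALIBRATION_KEYS, "calibration")
    calibration = Calibration(**calib_doc)

    params_doc = doc.get("parameters", {})
    _check_keys(params_doc, set(ALL_PARAMS), "parameters")
    missing = set(ALL_PARAMS) - set(params_doc)
    if missing:
        raise ConfigError(f"missing parameter(s): {sorted(missing)}")

    distributions: dict[str, ParameterDistribution] = {}
    values: dict[str, float] = {}
    for name, entry in params_doc.items():
        _check_keys(entry, _PARAM_KEYS, f"parameters.{name}")
        if "base" not in entry:
            raise ConfigError(f"parameters.{name} is missing its base value")
        dist = ParameterDistribution(
            family=str(entry.get("family", "fixed")),
            base_value=float(entry["base"]),
            shape_a=None if entry.get("shape_a") is None else float(entry["shape_a"]),
            shape_b=None if entry.get("shape_b") is None else float(entry["shape_b"]),
            range_low=None if entry.get("low") is None else float(entry["low"]),
            range_high=None if entry.get("high") is None else float(entry["high"]),
        )
        distributions[name] = dist
        values[name] = dist.base_value

    utilities = UtilitySet(**{attr: values[name] for name, attr in UTILITY_PARAMS.items()})
    costs = CostSet(**{attr: values[name] for name, attr in COST_PARAMS.items()})
    arms = {"sg": {}, "nsg": {}}
    for name, (which, attr) in TRANSITION_PARAMS.items():
        for arm in which:
            arms[arm][attr] = values[name]
    transitions = TransitionParameters(
        sg=StrategyTransitions(**arms["sg"]),
        nsg=StrategyTransitions(**arms["nsg"]),
    )

    spec = ModelSpec(
        utilities=utilities,
        costs=costs,
        transitions=transitions,
        distributions=distributions,
        settings=settings,
        calibration=calibration,
        life_table=_life_table_from_dict(doc.get("life_table", {}), base_dir),
    )
    problems = validate_model(spec)
    if problems:
        raise ConfigError("config failed validation: " + "; ".join(problems))
    return spec


def spec_to_dict(spec: ModelSpec) -> dict:
    """Serialize a spec to the config-document form (life table inlined as CSV
    is not supported here; synthetic tables round-trip by their recipe only if
    the spec was built from one, so the table is written as an embedded kind)."""
    params = {}
    for name in ALL_PARAMS:
        d = spec.distributions[name]
        entry: dict = {"base": d.base_value, "family": d.family}
        if d.range_low is not None:
            entry["low"] = d.range_low
        if d.range_high is not None:
            entry["high"] = d.range_high
        if d.shape_a is not None:
            entry["shape_a"] = d.shape_a
        if d.shape_b is not None:
            entry["shape_b"] = d.shape_b
        params[name] = entry
    calib = asdict(spec.calibration)
    calib["exam_states_sg"] = list(calib["exam_states_sg"])
    calib["exam_states_nsg"] = list(calib["exam_states_nsg"])
    return {
        "schema_version": SCHEMA_VERSION,
        "settings": asdict(spec.settings),
        "calibration": calib,
        "life_table": {"kind": "csv", "path": "life_table.csv"},
        "parameters": params,
    }


def load_spec(path: str | Path) -> ModelSpec:
    """Load and validate a model spec from a YAML config file."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return spec_from_dict(doc, base_dir=path.parent)


def save_spec(spec: ModelSpec, path: str | Path) -> None:
    """Write a spec to YAML, with its life table as a sibling CSV."""
    path = Path(path)
    doc = spec_to_dict(spec)
    write_life_table(spec.life_table, path.parent / "life_table.csv")
    path.write_text(yaml.safe_dump(doc, sort_keys=False))


def default_model() -> ModelSpec:
    """The bundled default parameterization of the screening decision model."""
    text = resources.files("thyrocea").joinpath("data/default_config.yaml").read_text()
    return spec_from_dict(yaml.safe_load(text))


def read_life_table(path: str | Path) -> LifeTable:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["age", "q"]:
        raise ConfigError(f"life table {path} must have columns age,q")
    return LifeTable(ages=df["age"].to_numpy(int), q=df["q"].to_numpy(float))


def write_life_table(table: LifeTable, path: str | Path) -> None:
    pd.DataFrame({"age": table.ages, "q": table.q}).to_csv(path, index=False)


@dataclass
class RunManifest:
    """Provenance record binding every output file to config, seed, version."""

    config_path: str
    config_sha256: str
    seed: int
    version: str
    timestamp: str
    calibration: dict
    outputs: list[str] = field(default_factory=list)

    @classmethod
    def create(cls, config_path: str | Path, seed: int, spec: ModelSpec) -> "RunManifest":
        from . import __version__

        digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
        calib = asdict(spec.calibration)
        calib = {k: list(v) if isinstance(v, tuple) else v for k, v in calib.items()}
        return cls(
            config_path=str(config_path),
            config_sha256=digest,
            seed=seed,
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
            calibration=calib,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())
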