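"""File I/O: catalyst-test logs (CSV), run configurations (YAML/JSON),
mechanism parameter files and machine-readable reports (JSON)."""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .microkinetics import AdsorptionParams, SurfaceStepParams
from .tof_estimation import CatalystTest

__all__ = [
    "read_test_log",
    "write_test_log",
    "packaged_test_log",
    "load_mechanism_params",
    "load_run_config",
    "write_report",
]

LOG_COLUMNS = ("test_id", "sachet_id", "use_count", "dP_loss_Pa", "dt_s", "T_tof_K")


class ParseError(ValueError):
    """Malformed log or configuration file."""


def read_test_log(path) -> list:
    """Parse a catalyst-test log CSV into :class:`CatalystTest` records.

    An empty file yields an empty list with a warning; missing columns or
    non-numeric fields raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty catalyst-test log: {path}")
        return []
    missing = set(LOG_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    tests = []
    # to_dict preserves per-column dtypes (iterrows would upcast to float)
    for line, row in enumerate(frame.to_dict("records"), start=2):
        try:
            tests.append(
                CatalystTest(
                    dp_loss=float(row["dP_loss_Pa"]),
                    duration=float(row["dt_s"]),
                    t_tof=float(row["T_tof_K"]),
                    sachet=str(row["sachet_id"]),
                    use_count=int(row["use_count"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}, line {line}: {exc}") from exc
    return tests


def write_test_log(tests, path) -> None:
    """Write catalyst tests back to CSV (lossless round-trip of all fields)."""
    rows = [
        {
            "test_id": i + 1,
            "sachet_id": t.sachet,
            "use_count": t.use_count,
            "dP_loss_Pa": t.dp_loss,
            "dt_s": t.duration,
            "T_tof_K": t.t_tof,
        }
        for i, t in enumerate(tests)
    ]
    pd.DataFrame(rows, columns=list(LOG_COLUMNS)).to_csv(path, index=False)


def packaged_test_log() -> list:
    """The packaged reference log of six real-time catalyst tests."""
    with resources.as_file(
        resources.files("jargas.data") / "catalyst_tests.csv"
    ) as path:
        return read_test_log(path)


def load_mechanism_params(path=None) -> dict:
    """Load microkinetic parameters from YAML (default: packaged Pd(111))."""
    if path is None:
        text = (resources.files("jargas.data") / "pd111.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    try:
        adsorption = {
            gas: AdsorptionParams(**entry) for gas, entry in raw["adsorption"].items()
        }
        surface = {
            name: SurfaceStepParams(**entry) for name, entry in raw["surface"].items()
        }
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"invalid mechanism parameter file: {exc}") from exc
    return {"adsorption": adsorption, "surface": surface}


_CONFIG_SECTIONS = {"exchange", "microkinetics", "tof", "es", "scherrer", "logging"}

_SECTION_KEYS = {
    "exchange": {"p_atm", "p_vac", "v_jar", "temperature", "r_gas", "cylinder",
                 "initial"},
    "microkinetics": {"model", "t_min", "t_max", "t_step", "total_pressure"},
    "tof": {"volume", "temperature"},
    "es": {"h", "a", "xi0", "alpha", "gamma", "epsilon", "max_iter"},
    "scherrer": {"shape_factor", "wavelength"},
    "logging": {"verbosity"},
}


def load_run_config(path) -> dict:
    """Load a nested run configuration (YAML or JSON), rejecting unknown
    sections and keys.  Pressures are Pa, volumes m^3, temperatures K."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _CONFIG_SECTIONS
    if unknown:
        raise ParseError(f"{path}: unknown sections {sorted(unknown)}")
    for section, entries in raw.items():
        bad = set(entries or {}) - _SECTION_KEYS[section]
        if bad:
            raise ParseError(f"{path}: unknown keys {sorted(bad)} in [{section}]")
    return raw


def write_report(result: dict, path) -> None:
    """Write a machine-readable result report as indented JSON."""

    def _default(obj):
        try:
            return obj.item()
        except (AttributeError, ValueError):
            return list(obj)

    Path(path).write_text(json.dumps(result, indent=2, default=_default) + "\n")
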