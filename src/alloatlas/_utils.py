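"""Shared helpers: deterministic seeding and cell-table state tracking."""

from __future__ import annotations

import numpy as np
import pandas as pd

#: processing states a cell table moves through
STATES = ("raw", "transformed", "standardized")

#: columns every cell table must carry besides the marker channels
META_COLUMNS = ("cell_id", "roi", "patient", "group", "x", "y")

#: clinical outcome groups of the study design
GROUPS = ("NR", "TCMR", "CR")


class ConfigurationError(ValueError):
    """Invalid parameter or configuration file."""


class DataError(ValueError):
    """Input data violates a contract (negative intensity, bad schema...)."""


def derived_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Independent, order-insensitive random stream for a (stage, unit) key.

    All randomness in the package flows from a single master seed through
    ``SeedSequence`` spawn keys, so reruns are bit-stable and units
    (patients, ROIs, bootstrap iterations) can be generated in any order.
    """
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key)))


def derived_int_seed(master_seed: int, *key: int) -> int:
    """A plain integer seed (< 2**31) derived deterministically, for sklearn."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def get_state(table: pd.DataFrame) -> str:
    return table.attrs.get("state", "raw")


def set_state(table: pd.DataFrame, state: str) -> pd.DataFrame:
    if state not in STATES:
        raise ConfigurationError(f"unknown processing state {state!r}")
    table.attrs["state"] = state
    return table


def marker_columns(table: pd.DataFrame) -> list[str]:
    """Marker channels = every column that is not a metadata column."""
    return [c for c in table.columns if c not in META_COLUMNS]


def require_state(table: pd.DataFrame, expected: str, op: str) -> None:
    state = get_state(table)
    if state != expected:
        raise DataError(f"{op} expects a table in state {expected!r}, got {state!r}")
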