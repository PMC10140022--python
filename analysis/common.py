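"""Shared plumbing for the numbered analysis scripts.

Each script is a thin driver over :mod:`brainage`; intermediate
artifacts (volumes, trained models, fold predictions) live under
``scratch/study/`` and the human-readable tables under ``results/``.
Scripts must be run in order (01 -> 06) for a given seed.
"""

from __future__ import annotations

import argparse
import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from brainage.pipeline import default_study_config, derive_seed

REPO = Path(__file__).resolve().parents[1]
SCRATCH = REPO / "scratch" / "study"
RESULTS = REPO / "results" / "study"


def parse_seed(description: str) -> int:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1, help="master seed")
    return parser.parse_args().seed


def study_config(seed: int):
    return default_study_config(master_seed=derive_seed(seed, "analysis"))


def save_array(name: str, arr: np.ndarray) -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    np.save(SCRATCH / f"{name}.npy", arr)


def load_array(name: str) -> np.ndarray:
    return np.load(SCRATCH / f"{name}.npy")


def save_table(name: str, frame: pd.DataFrame) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / f"{name}.csv"
    frame.to_csv(path, index=False)
    return path


def load_table(name: str) -> pd.DataFrame:
    return pd.read_csv(RESULTS / f"{name}.csv")


def save_json(name: str, payload: dict) -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    (SCRATCH / f"{name}.json").write_text(json.dumps(payload, indent=2, default=str))


def load_json(name: str) -> dict:
    return json.loads((SCRATCH / f"{name}.json").read_text())
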