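"""Shared helpers for the numbered analysis drivers."""

from __future__ import annotations

from pathlib import Path

from cssig.data_model import load_collection
from cssig.synthetic_data import generate_collection

ROOT = Path(__file__).resolve().parent.parent
SIM_DIR = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def load_or_generate(seed: int):
    """Load the simulated collection written by 01_simulate, else regenerate.

    Regeneration uses the same seed, so downstream scripts are reproducible
    whether or not the on-disk copy exists.
    """
    manifest = SIM_DIR / "collection.yaml"
    if manifest.exists():
        collection, metabolites = load_collection(manifest)
        return collection, metabolites
    collection, metabolites, _ = generate_collection(seed=seed)
    return collection, metabolites
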