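"""Shared driver plumbing: one seeded configuration, one output root.

Each numbered script regenerates the synthetic study inputs from the seed
(generation is cheap and bit-deterministic), runs its stage through the
library, prints what it found, and writes tables under results/.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from gliotopo import PipelineConfig, SyntheticConfig
from gliotopo import fixtures


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    return parser.parse_args()


def study(seed: int):
    """Default-condition synthetic study: config, parcellation, truth fields."""
    config = PipelineConfig(synthetic=SyntheticConfig(seed=seed))
    parc = fixtures.make_parcellation(config.synthetic)
    truth = fixtures.make_ground_truth_fields(config.synthetic, parc)
    return config, parc, truth
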