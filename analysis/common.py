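"""Shared study configuration for the numbered analysis scripts.

All scripts operate on one pipeline output directory (results/pipeline) so
later steps pick up earlier steps' files; rerunning a script regenerates
only its own stage (the pipeline driver resumes from content hashes).
"""

from pathlib import Path

from megdiverge.config import PipelineConfig, config_from_dict

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def build_config(seed: int = SEED) -> PipelineConfig:
    return config_from_dict({
        "seed": seed,
        "out_dir": str(RESULTS / "pipeline"),
        "sim": {"n_words": 2000, "n_sentences": 400, "n_channels": 20,
                "n_timebins": 10, "embed_dim": 16},
        "discovery": {"n_perm": 999},
        "comparison": {"n_perm": 10000},
        "mc": {"n_items": 300, "epochs": 30},
    })
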