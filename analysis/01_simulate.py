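#!/usr/bin/env python
"""Generate the synthetic study session.

A seeded session of 2000 words over 400 sentences: context-dependent
embeddings (three candidate layers, the middle one generating the
responses), MEG-like responses from a linear forward model plus unit
Gaussian noise, a planted category (30% of sentences, marked by a keyword)
whose responses carry a structured residual at three times the noise level,
and a 300-item toy multiple-choice task. Writes events.tsv, sim_data.h5,
ground_truth.json and mc_items.json under results/pipeline.
"""

from pathlib import Path

from common import build_config

from megdiverge.pipeline import _run_simulate

cfg = build_config()
out = Path(cfg.out_dir)
out.mkdir(parents=True, exist_ok=True)
_run_simulate(cfg, out)

import pandas as pd

events = pd.read_csv(out / "events.tsv", sep="\t", keep_default_na=False)
n_planted = (events["categories"].str.contains("planted")).sum()
print(f"wrote {len(events)} word events over {events['sentence_id'].nunique()} "
      f"sentences to {out}")
print(f"{n_planted} words carry the planted flag "
      f"({100 * n_planted / len(events):.1f}%)")
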