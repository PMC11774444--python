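"""Readers and writers for the pipeline's on-disk formats.

Tables are UTF-8 TSV with a header line; sentence corpora are one sentence
per line; array data (embeddings, response tensors, encoding results) live
in one HDF5 container per stage. Datasets are written with
``track_times=False`` so a rerun with the same seed produces byte-identical
files — the pipeline's resume logic and the determinism guarantee both hash
file contents.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .divergence import ChannelSet, ContrastCorpora, DivergenceTable
from .encoding import EncodingResult
from .simulate import GroundTruth, WordEvent, events_to_records

EVENT_COLUMNS = ["word_id", "token", "sentence_id", "position", "categories"]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for block in iter(lambda: f.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


# ---------------------------------------------------------------- events TSV


def write_events_tsv(events: list[WordEvent], path) -> None:
    df = pd.DataFrame(events_to_records(events), columns=EVENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> list[WordEvent]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"categories": str})
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    return [
        WordEvent(
            word_id=int(r.word_id),
            token=str(r.token),
            sentence_id=int(r.sentence_id),
            position_in_sentence=int(r.position),
            category_flags=frozenset(
                c for c in str(r.categories).split(",") if c
            ),
        )
        for r in df.itertuples()
    ]


# ------------------------------------------------------------ HDF5 containers


def _ds(group, name, data) -> None:
    group.create_dataset(name, data=np.asarray(data), track_times=False)


def write_sim_h5(
    path,
    layers: list[np.ndarray],
    responses: np.ndarray,
    truth: GroundTruth,
) -> None:
    """Stage container: ``embeddings/layer<k>``, ``responses`` and the
    ground-truth arrays (weights, bias, planted amplitudes/patterns)."""
    with h5py.File(path, "w", track_order=True) as f:
        g = f.create_group("embeddings", track_order=True)
        for k, L in enumerate(layers):
            _ds(g, f"layer{k}", L)
        _ds(f, "responses", responses)
        f["responses"].attrs["shape"] = responses.shape
        gt = f.create_group("ground_truth", track_order=True)
        _ds(gt, "weights", truth.true_weights)
        _ds(gt, "bias", truth.true_bias)
        if truth.planted_amplitudes is not None:
            _ds(gt, "planted_amplitudes", truth.planted_amplitudes)
            _ds(gt, "planted_patterns", truth.planted_patterns)


def read_sim_h5(path):
    """Returns (layers, responses, truth-without-ids)."""
    with h5py.File(path, "r") as f:
        g = f["embeddings"]
        layers = [g[f"layer{k}"][()] for k in range(len(g))]
        responses = f["responses"][()]
        gt = f["ground_truth"]
        truth = GroundTruth(
            true_weights=gt["weights"][()],
            true_bias=gt["bias"][()],
            planted_word_ids=frozenset(),
            planted_keyword="",
            noise_sd=float("nan"),
            planted_amplitudes=(
                gt["planted_amplitudes"][()] if "planted_amplitudes" in gt else None
            ),
            planted_patterns=(
                gt["planted_patterns"][()] if "planted_patterns" in gt else None
            ),
        )
    return layers, responses, truth


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_jsonable(), indent=1) + "\n")


def write_encoding_h5(path, results: dict[int, EncodingResult]) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        for layer, res in sorted(results.items()):
            g = f.create_group(f"layer{layer}", track_order=True)
            _ds(g, "predicted", res.predicted)
            _ds(g, "correlations", res.correlations)
            _ds(g, "chosen_lambdas", res.chosen_lambdas)


def read_encoding_h5(path) -> dict[int, EncodingResult]:
    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            layer = int(name.removeprefix("layer"))
            g = f[name]
            out[layer] = EncodingResult(
                predicted=g["predicted"][()],
                correlations=g["correlations"][()],
                chosen_lambdas=g["chosen_lambdas"][()],
                layer_index=layer,
            )
    return out


# ------------------------------------------------------------ divergence I/O


def write_word_mse_tsv(table: DivergenceTable, events, path) -> None:
    df = pd.DataFrame(
        {
            "word_id": [e.word_id for e in events],
            "token": [e.token for e in events],
            "sentence_id": [e.sentence_id for e in events],
            "mse": table.word_mse,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_sentences_ranked_tsv(table: DivergenceTable, sentences, path) -> None:
    df = pd.DataFrame(
        {
            "rank": np.arange(len(table.ranking)),
            "sentence_id": table.ranking,
            "mean_mse": [table.sentence_mse.loc[s] for s in table.ranking],
            "sentence": [sentences[s] for s in table.ranking],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_corpus_txt(sentences: list[str], path) -> None:
    Path(path).write_text("\n".join(sentences) + "\n")


def read_corpus_txt(path) -> list[str]:
    return [l for l in Path(path).read_text().splitlines() if l.strip()]


def write_channel_set_json(S: ChannelSet, path) -> None:
    payload = {
        "alpha": S.alpha,
        "n_words": S.n_words,
        "pool": S.pool,
        "n_significant": S.size,
        "grid_shape": list(S.members.shape),
        "members": [[int(c), int(t)] for c, t in S.pairs()],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_channel_set_json(path) -> ChannelSet:
    d = json.loads(Path(path).read_text())
    mask = np.zeros(tuple(d["grid_shape"]), dtype=bool)
    for c, t in d["members"]:
        mask[c, t] = True
    return ChannelSet(
        members=mask, alpha=d["alpha"], n_words=d["n_words"], pool=d["pool"]
    )


def write_contrast(corpora: ContrastCorpora, out_dir) -> None:
    out = Path(out_dir)
    write_corpus_txt(corpora.d0_sentences, out / "d0.txt")
    write_corpus_txt(corpora.d1_sentences, out / "d1.txt")


# ------------------------------------------------------------- discovery I/O


def write_hypotheses_tsv(hypotheses, path) -> None:
    df = pd.DataFrame(
        {
            "rank": np.arange(1, len(hypotheses) + 1),
            "hypothesis": [h.text for h in hypotheses],
            "validity": [h.validity for h in hypotheses],
            "p_value": [h.p_value for h in hypotheses],
            "fold_validities": [
                ";".join(f"{v:.6g}" for v in h.fold_validities) for h in hypotheses
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ comparison I/O


def write_channel_comparison_tsv(comp, path) -> None:
    rows = []
    C, T = comp.delta_r.shape
    for c in range(C):
        for t in range(T):
            rows.append(
                {
                    "channel": c,
                    "timebin": t,
                    "delta_r": comp.delta_r[c, t],
                    "p_value": comp.p_values[c, t],
                    "label": comp.labels[c, t],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
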