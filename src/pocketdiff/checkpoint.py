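"""Versioned checkpoint I/O: parameters + noise schedule + vocabulary.

A checkpoint is a single ``.npz`` holding every parameter array plus a JSON
metadata blob (format version, network config, schedule, vocabulary, config
hash), so sampling is fully reproducible from the checkpoint alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .chem_core import AtomTypeVocabulary
from .diffusion import NoiseSchedule
from .network import NetworkConfig, NetworkParams

FORMAT_VERSION = 1

__all__ = ["save_checkpoint", "load_checkpoint"]


def _vocab_dict(vocab: AtomTypeVocabulary) -> dict:
    return {
        "elements": list(vocab.elements),
        "vdw_radius": dict(vocab.vdw_radius),
        "hydrophobic": sorted(vocab.hydrophobic),
        "hbond_donor": sorted(vocab.hbond_donor),
        "hbond_acceptor": sorted(vocab.hbond_acceptor),
    }


def _vocab_from_dict(d: dict) -> AtomTypeVocabulary:
    return AtomTypeVocabulary(
        elements=tuple(d["elements"]),
        vdw_radius=dict(d["vdw_radius"]),
        hydrophobic=frozenset(d["hydrophobic"]),
        hbond_donor=frozenset(d["hbond_donor"]),
        hbond_acceptor=frozenset(d["hbond_acceptor"]),
    )


def save_checkpoint(path: str | Path, theta: NetworkParams,
                    sched: NoiseSchedule, vocab: AtomTypeVocabulary) -> None:
    cfg = asdict(theta.config)
    meta = {
        "format_version": FORMAT_VERSION,
        "network_config": cfg,
        "schedule": sched.to_dict(),
        "vocabulary": _vocab_dict(vocab),
    }
    meta["config_hash"] = hashlib.sha256(
        json.dumps(meta, sort_keys=True).encode()
    ).hexdigest()
    arrays = {f"param/{k}": v for k, v in theta.flat().items()}
    np.savez(str(path), __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path):
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"unsupported checkpoint format {meta.get('format_version')}"
            )
        cfg = NetworkConfig(**meta["network_config"])
        omega, head_type, head_affinity = {}, {}, {}
        for key in data.files:
            if not key.startswith("param/"):
                continue
            group, name = key[len("param/"):].split(".", 1)
            {"omega": omega, "head_type": head_type,
             "head_affinity": head_affinity}[group][name] = data[key]
    theta = NetworkParams(omega, head_type, head_affinity, cfg)
    sched = NoiseSchedule.from_dict(meta["schedule"])
    vocab = _vocab_from_dict(meta["vocabulary"])
    return theta, sched, vocab
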