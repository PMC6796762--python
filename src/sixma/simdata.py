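"""Synthetic 41-nt adenine-centred datasets with a tunable planted signal.

Real 6mA benchmark sets are balanced collections of 41-nt windows whose
central adenine is either methylated (positives, called from SMRT
kinetics) or drawn from GAGG-containing coding sequence (negatives).
This generator emulates that *structure* so the whole pipeline can be
exercised without downloads: windows are sampled i.i.d. from a
background base distribution, the central base is forced to adenine,
and a short motif (GAGG by default, the context at which plant 6mA is
enriched) is implanted at a random offset with a class-specific rate.
Positives may additionally receive a per-position base-frequency bias
around the centre, loosely mimicking a consensus context; none of the
parameters are claimed to be biologically calibrated.

The motif offset is sampled so the motif never overlaps the central
adenine, preserving the window contract.  Everything is reproducible
from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .seqio import CENTER_INDEX, WINDOW_LENGTH, LabeledDataset, SequenceRecord

__all__ = [
    "SimConfig",
    "DEFAULT_BACKGROUND",
    "centered_ag_bias",
    "strong_signal_config",
    "generate",
    "null_dataset",
]

_ACGT = "ACGT"

#: Uniform background base frequencies (A, C, G, T).
DEFAULT_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


def centered_ag_bias(
    halfwidth: int = 6, p_ag: float = 0.42
) -> dict[int, tuple[float, float, float, float]]:
    """Default positional bias for positives: A/G-enriched flanks.

    Applies to the ``2 * halfwidth`` flank positions within
    ``halfwidth`` of the central adenine (the centre itself is always
    adenine).  Each biased position uses base frequencies
    (A, C, G, T) = (p_ag, p_ct, p_ag, p_ct) with p_ct = 0.5 - p_ag.
    """
    if not 0.25 <= p_ag <= 0.5:
        raise ValueError("p_ag must lie in [0.25, 0.5]")
    p_ct = 0.5 - p_ag
    probs = (p_ag, p_ct, p_ag, p_ct)
    positions = [
        p
        for p in range(CENTER_INDEX - halfwidth + 1, CENTER_INDEX + halfwidth + 2)
        if p != CENTER_INDEX + 1
    ]  # 1-based, centre excluded
    return {p: probs for p in positions}


@dataclass
class SimConfig:
    """Generative settings for one synthetic dataset."""

    n_pos: int = 400
    n_neg: int = 400
    motif: str = "GAGG"
    motif_rate_pos: float = 0.9
    motif_rate_neg: float = 0.1
    positional_bias: Optional[dict] = None  # 1-based position -> (pA,pC,pG,pT)
    background: tuple[float, float, float, float] = DEFAULT_BACKGROUND
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.motif_rate_pos, self.motif_rate_neg):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("motif rates must lie in [0, 1]")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if set(self.motif) - set(_ACGT):
            raise ValueError("motif must be over {A, C, G, T}")
        if len(self.motif) > CENTER_INDEX:
            raise ValueError(
                f"motif longer than the flank ({CENTER_INDEX} nt) cannot be "
                "implanted without touching the central adenine"
            )

    def to_json(self) -> str:
        d = {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "motif": self.motif,
            "motif_rate_pos": self.motif_rate_pos,
            "motif_rate_neg": self.motif_rate_neg,
            "positional_bias": (
                {str(k): list(v) for k, v in self.positional_bias.items()}
                if self.positional_bias
                else None
            ),
            "background": list(self.background),
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)


def strong_signal_config(n_pos: int = 400, n_neg: int = 400, seed: int = 0) -> SimConfig:
    """The strong-signal study condition: GAGG in 90% of positives and
    10% of negatives, plus the default A/G centre bias in positives."""
    return SimConfig(
        n_pos=n_pos,
        n_neg=n_neg,
        motif_rate_pos=0.9,
        motif_rate_neg=0.1,
        positional_bias=centered_ag_bias(),
        seed=seed,
    )


def _allowed_motif_starts(motif_len: int) -> np.ndarray:
    starts = [
        s
        for s in range(WINDOW_LENGTH - motif_len + 1)
        if not (s <= CENTER_INDEX <= s + motif_len - 1)
    ]
    return np.asarray(starts, dtype=int)


def _position_probs(config: SimConfig, biased: bool) -> np.ndarray:
    probs = np.tile(np.asarray(config.background, dtype=float), (WINDOW_LENGTH, 1))
    if biased and config.positional_bias:
        for pos_1based, p in config.positional_bias.items():
            p = np.asarray(p, dtype=float)
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"bias at position {pos_1based} does not sum to 1")
            probs[int(pos_1based) - 1] = p
    return probs


def _sample_class(
    rng: np.random.Generator,
    n: int,
    config: SimConfig,
    motif_rate: float,
    biased: bool,
    prefix: str,
    label: int,
) -> list[SequenceRecord]:
    probs = _position_probs(config, biased)
    cum = probs.cumsum(axis=1)
    u = rng.random((n, WINDOW_LENGTH))
    base_idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    base_idx[:, CENTER_INDEX] = 0  # force central adenine
    implant = rng.random(n) < motif_rate
    starts = _allowed_motif_starts(len(config.motif))
    offsets = rng.integers(0, len(starts), size=n)
    motif_idx = [_ACGT.index(b) for b in config.motif]
    records = []
    for i in range(n):
        row = base_idx[i]
        if implant[i]:
            s = starts[offsets[i]]
            row[s : s + len(config.motif)] = motif_idx
        seq = "".join(_ACGT[j] for j in row)
        records.append(
            SequenceRecord(id=f"{prefix}{i:05d}", seq=seq, label=label)
        )
    return records


def generate(config: SimConfig) -> LabeledDataset:
    """Draw a balanced-by-construction synthetic dataset.

    Positives and negatives share the background process; the class
    signal is the difference in motif implant rate plus (optionally)
    the positional bias applied to positives only.
    """
    rng = np.random.default_rng(config.seed)
    pos = _sample_class(
        rng, config.n_pos, config, config.motif_rate_pos, biased=True,
        prefix="pos_", label=1,
    )
    neg = _sample_class(
        rng, config.n_neg, config, config.motif_rate_neg, biased=False,
        prefix="neg_", label=0,
    )
    return LabeledDataset(pos + neg)


def null_dataset(n: int, seed: int = 0) -> LabeledDataset:
    """A no-signal dataset: both classes drawn from the identical process.

    Motif implant rate 0.1 for both classes, no positional bias.  Any
    pipeline evaluated on this data should sit at chance accuracy;
    departures indicate leakage or an evaluation bug.
    """
    if n % 2 != 0:
        raise ValueError("n must be even (balanced classes)")
    config = SimConfig(
        n_pos=n // 2,
        n_neg=n // 2,
        motif_rate_pos=0.1,
        motif_rate_neg=0.1,
        positional_bias=None,
        seed=seed,
    )
    return generate(config)
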