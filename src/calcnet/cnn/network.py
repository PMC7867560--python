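"""The three candidate 2.5D network architectures.

All three take a 3-channel p x p patch triplet (axial, coronal, sagittal as
channels) and end in a 2-way softmax (index 0 = phlebolith, 1 = stone):

* A — Conv 16@3x3 / AvgPool 2 / FC 64 / FC 2
* B — Conv 16@5x5 / AvgPool 2 / FC 128 / FC 64 / FC 2
* C — Conv 24@3x3 / AvgPool 2 / Conv 48@3x3 / AvgPool 2 / FC 96 / FC 2

with ReLU activations throughout.  Candidate C, the only one with two
convolutional layers, is the default for the full pipeline; its filter
widths were selected on the synthetic benchmark (narrower nets under-use
the fainter class signs, and roughly double the width gains little for
twice the cost).  Only the layer topology defines a candidate; widths are
configurable through this table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..core import CalcnetError
from .layers import (AvgPool2D, Conv2D, Dense, Dropout, Flatten, Layer,
                     ReLU, softmax)

STONE_INDEX = 1  # softmax output column holding the stone probability

_CANDIDATES = {
    "A": [("conv", 16, 3), ("pool", 2), ("fc", 64), ("fc", 2)],
    "B": [("conv", 16, 5), ("pool", 2), ("fc", 128), ("fc", 64), ("fc", 2)],
    "C": [("conv", 24, 3), ("pool", 2), ("conv", 48, 3), ("pool", 2),
          ("fc", 96), ("fc", 2)],
}


@dataclass
class NetworkSpec:
    """Declarative description of one candidate architecture."""

    candidate: str
    layers: list[tuple] = field(default_factory=list)
    patch_size: int = 31
    in_channels: int = 3

    @property
    def n_conv_layers(self) -> int:
        return sum(1 for l in self.layers if l[0] == "conv")


def network_spec(candidate: str, patch_size: int = 31) -> NetworkSpec:
    cand = str(candidate).upper()
    if cand not in _CANDIDATES:
        raise CalcnetError(f"unknown candidate {candidate!r}; expected A, B or C")
    return NetworkSpec(cand, list(_CANDIDATES[cand]), int(patch_size))


class Network:
    """A concrete, trainable instance of one candidate architecture."""

    def __init__(self, spec: NetworkSpec, seed: int = 0,
                 dropout: float = 0.25) -> None:
        self.spec = spec
        self.seed = int(seed)
        self.dropout = float(dropout)
        rng = np.random.default_rng(self.seed)
        self.layers: list[Layer] = []
        c, h = spec.in_channels, spec.patch_size
        flat = None
        for desc in spec.layers:
            if desc[0] == "conv":
                _, nf, k = desc
                self.layers.append(Conv2D(c, nf, k, rng,
                                          needs_input_grad=bool(self.layers)))
                self.layers.append(ReLU())
                c, h = nf, h - k + 1
            elif desc[0] == "pool":
                self.layers.append(AvgPool2D(desc[1]))
                h = h // desc[1]
            elif desc[0] == "fc":
                if flat is None:
                    self.layers.append(Flatten())
                    flat = c * h * h
                width = desc[1]
                if desc is spec.layers[-1] and self.dropout > 0:
                    self.layers.append(Dropout(self.dropout, seed=self.seed))
                self.layers.append(Dense(flat, width, rng))
                if desc is not spec.layers[-1]:
                    self.layers.append(ReLU())
                flat = width
            else:  # pragma: no cover
                raise CalcnetError(f"unknown layer descriptor {desc}")
            if h < 1:
                raise CalcnetError(
                    f"patch_size {spec.patch_size} too small for candidate "
                    f"{spec.candidate}: spatial size collapsed")
        if flat != 2:
            raise CalcnetError("architecture must end in a 2-way output")

    @property
    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch (N, 3, p, p)."""
        out = np.asarray(x, dtype=np.float32)
        for l in self.layers:
            if isinstance(l, Dropout):
                l.train_mode = train
            out = l.forward(out)
        return out

    def reset_dropout(self) -> None:
        for l in self.layers:
            if isinstance(l, Dropout):
                l.reset()

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for l in reversed(self.layers):
            d = l.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """(N, 2) softmax probabilities, computed in inference batches."""
        x = np.asarray(x, dtype=np.float32)
        outs = [softmax(self.forward(x[i:i + batch_size]))
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs) if outs else np.empty((0, 2))

    def checksum(self) -> float:
        """Order-stable scalar digest of all weights (for determinism checks)."""
        return float(sum(np.abs(p).sum() for p in self.params))

    # -- persistence ----------------------------------------------------
    def save(self, directory: str | Path, extra: dict | None = None) -> None:
        """Weights as .npz plus a JSON sidecar with the architecture."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz",
                 **{f"p{i}": p for i, p in enumerate(self.params)})
        meta = {"candidate": self.spec.candidate,
                "dropout": self.dropout,
                "patch_size": self.spec.patch_size,
                "in_channels": self.spec.in_channels,
                "seed": self.seed}
        meta.update(extra or {})
        (d / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> tuple["Network", dict]:
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        net = cls(network_spec(meta["candidate"], meta["patch_size"]),
                  seed=meta.get("seed", 0), dropout=meta.get("dropout", 0.25))
        with np.load(d / "weights.npz") as z:
            for i, p in enumerate(net.params):
                p[...] = z[f"p{i}"]
        return net, meta


def build_network(candidate: str, patch_size: int = 31, seed: int = 0,
                  dropout: float = 0.25) -> Network:
    """Initialise one of the three candidates with deterministic weights."""
    return Network(network_spec(candidate, patch_size), seed=seed,
                   dropout=dropout)
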