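"""Single-file checkpoint container: weights + config echo + vocabulary + metadata.

Serialized with pickle over a canonically ordered payload, so a loaded
checkpoint re-saves to bit-identical bytes.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

FORMAT_VERSION = 1


class CheckpointError(ValueError):
    pass


@dataclass
class Checkpoint:
    kind: str                       # "contrastive" | "generator" | "cpi"
    state: dict[str, np.ndarray]
    config: dict
    vocab_tokens: list[str]
    protein_vocab_tokens: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def _payload(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "kind": self.kind,
            "state": {k: self.state[k] for k in sorted(self.state)},
            "config": self.config,
            "vocab_tokens": list(self.vocab_tokens),
            "protein_vocab_tokens": (
                list(self.protein_vocab_tokens)
                if self.protein_vocab_tokens is not None else None
            ),
            "metadata": self.metadata,
        }

    def save(self, path: str | Path):
        Path(path).write_bytes(pickle.dumps(self._payload(), protocol=4))

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        try:
            payload = pickle.loads(Path(path).read_bytes())
        except Exception as exc:  # noqa: BLE001 - normalize to one error type
            raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
        if not isinstance(payload, dict) or payload.get("format_version") != FORMAT_VERSION:
            raise CheckpointError(f"{path} is not a recognized checkpoint")
        return cls(
            kind=payload["kind"],
            state=payload["state"],
            config=payload["config"],
            vocab_tokens=payload["vocab_tokens"],
            protein_vocab_tokens=payload["protein_vocab_tokens"],
            metadata=payload["metadata"],
        )
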