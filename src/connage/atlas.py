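"""Component atlas: the labeling of independent components into functional networks.

The default atlas follows the NeuroMark fMRI 1.0 template of 53 spatially
constrained ICA components grouped into seven canonical networks: subcortical
(SCN), auditory (AUD), sensorimotor (SMN), visual (VSN), cognitive control
(CCN), default mode (DMN) and cerebellar (CBN). Membership is data (a bundled
two-column CSV), not code, so alternative templates can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

NETWORK_ORDER = ("SCN", "AUD", "SMN", "VSN", "CCN", "DMN", "CBN")


@dataclass(frozen=True)
class ComponentAtlas:
    """Ordered component labels and their network assignment.

    Attributes
    ----------
    component_ids : tuple of str
        Component labels in matrix row/column order.
    network_of : dict
        Map component id -> network label.
    """

    component_ids: tuple[str, ...]
    network_of: dict

    def __post_init__(self) -> None:
        missing = [c for c in self.component_ids if c not in self.network_of]
        if missing:
            raise ValueError(f"components without a network assignment: {missing}")

    @property
    def networks(self) -> tuple[str, ...]:
        """Network labels in canonical order (only those present)."""
        present = {self.network_of[c] for c in self.component_ids}
        ordered = [n for n in NETWORK_ORDER if n in present]
        ordered += sorted(present - set(NETWORK_ORDER))
        return tuple(ordered)

    @property
    def n_components(self) -> int:
        return len(self.component_ids)

    def network_indices(self, network: str) -> np.ndarray:
        """Row/column indices of one network's components, order preserved."""
        if network not in self.networks:
            raise KeyError(
                f"unknown network {network!r}; valid labels: {list(self.networks)}"
            )
        return np.array(
            [i for i, c in enumerate(self.component_ids) if self.network_of[c] == network],
            dtype=int,
        )

    def network_sizes(self) -> dict:
        return {n: int(len(self.network_indices(n))) for n in self.networks}

    @classmethod
    def from_csv(cls, path) -> "ComponentAtlas":
        """Read a two-column (component_id, network) CSV."""
        table = pd.read_csv(path)
        for col in ("component_id", "network"):
            if col not in table.columns:
                raise ValueError(f"atlas file missing required column {col!r}")
        ids = tuple(table["component_id"].astype(str))
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate component ids in atlas file")
        return cls(ids, dict(zip(ids, table["network"].astype(str))))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"component_id": self.component_ids,
             "network": [self.network_of[c] for c in self.component_ids]}
        ).to_csv(path, index=False)

    def subset(self, n_components: int) -> "ComponentAtlas":
        """First ``n_components`` entries — used for reduced-scale simulations."""
        ids = self.component_ids[:n_components]
        return ComponentAtlas(ids, {c: self.network_of[c] for c in ids})


def load_default_atlas() -> ComponentAtlas:
    """The bundled 53-component / 7-network NeuroMark fMRI 1.0 labeling."""
    with resources.as_file(
        resources.files("connage.data").joinpath("neuromark_fmri10.csv")
    ) as path:
        return ComponentAtlas.from_csv(Path(path))


def uniform_atlas(n_components: int, n_networks: int = 7) -> ComponentAtlas:
    """Synthetic atlas splitting ``n_components`` as evenly as possible into networks.

    Useful for reduced-scale cohorts where the 53-component template is too
    large; networks take labels from the canonical seven in order.
    """
    if n_networks > len(NETWORK_ORDER):
        raise ValueError(f"at most {len(NETWORK_ORDER)} networks supported")
    sizes = np.full(n_networks, n_components // n_networks, dtype=int)
    sizes[: n_components % n_networks] += 1
    ids, membership = [], {}
    for net, size in zip(NETWORK_ORDER, sizes):
        for i in range(size):
            cid = f"{net}_{i + 1:02d}"
            ids.append(cid)
            membership[cid] = net
    return ComponentAtlas(tuple(ids), membership)
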