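"""Pluggable stability-change (ddG) prediction.

Sign convention throughout: negative ddG (kcal/mol) = stabilising.

Two predictors are provided behind one duck-typed interface
(``predictor.ddg(mutation, context) -> DdgEstimate``):

* :class:`SurrogateDdgPredictor` — a deterministic, transparent energy
  model over burial, hydropathy, packing volume and backbone terms,
  with optional explicit pairwise-interaction terms so that
  context-dependent (non-additive) scenarios can be scripted.
* :class:`TableDdgPredictor` — an adapter over a CSV of externally
  computed values (e.g. from a physics-based energy function), with
  replicate aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .data import HYDROPATHY_Z, RESIDUE_VOLUME
from .structure import ContactMap, ResidueKey


@dataclass(frozen=True)
class DdgEstimate:
    """A ddG prediction with replicate statistics and chain multiplicity."""

    mean: float  # kcal/mol, negative = stabilising
    sd: float = 0.0
    n_runs: int = 1
    propagated: float = None  # mean x chain multiplicity

    def __post_init__(self):
        if self.propagated is None:
            object.__setattr__(self, "propagated", self.mean)
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def propagate_multiplicity(estimate: DdgEstimate, group_size: int) -> DdgEstimate:
    """Scale a single-chain ddG by the number of identical chains."""
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    return replace(estimate, propagated=estimate.mean * group_size)


class SurrogateDdgPredictor:
    """Deterministic burial-weighted ddG surrogate.

    With burial ``b = 1 - exposure`` of the mutated site::

        ddG = c_h * b * (h_wt - h_mut)
            + c_v * b * max(0, V_mut - V_wt) / 100
            + c_P * [mut == P] + c_G * [wt == G]
            + sum of pair terms with in-contact context mutations

    where ``h`` is the z-scored hydropathy and ``V`` the residue volume
    in cubic Angstrom.  Burying hydrophobics stabilises; over-packing,
    proline introduction and glycine removal destabilise.  ``pair_terms``
    maps frozensets of two residue keys to an extra ddG contribution
    applied only when the partner mutation is already in context and the
    two sites are in structural contact.
    """

    def __init__(
        self,
        exposure: Mapping[ResidueKey, float],
        contact_map: Optional[ContactMap] = None,
        pair_terms: Optional[Mapping[frozenset, float]] = None,
        c_hydropathy: float = 0.8,
        c_volume: float = 1.0,
        c_proline: float = 1.0,
        c_glycine: float = 0.5,
        n_runs: int = 3,
    ):
        self.exposure = exposure
        self.contact_map = contact_map
        self.pair_terms = dict(pair_terms or {})
        self.c_hydropathy = c_hydropathy
        self.c_volume = c_volume
        self.c_proline = c_proline
        self.c_glycine = c_glycine
        self.n_runs = int(n_runs)

    def ddg(self, mutation, context: Iterable = ()) -> DdgEstimate:
        wt, mut, site = mutation.wt, mutation.mut, mutation.site
        if wt not in HYDROPATHY_Z or mut not in HYDROPATHY_Z:
            raise ValueError(f"unknown residue type in mutation {mutation}")
        if mut == wt:
            return DdgEstimate(0.0, 0.0, self.n_runs)
        burial = 1.0 - float(self.exposure.get(site, 0.0))
        value = (
            self.c_hydropathy * burial * (HYDROPATHY_Z[wt] - HYDROPATHY_Z[mut])
            + self.c_volume
            * burial
            * max(0.0, RESIDUE_VOLUME[mut] - RESIDUE_VOLUME[wt])
            / 100.0
            + (self.c_proline if mut == "P" else 0.0)
            + (self.c_glycine if wt == "G" else 0.0)
        )
        for other in context:
            pair = frozenset((site, other.site))
            if pair not in self.pair_terms:
                continue
            if self.contact_map is None or self.contact_map.in_contact(
                site, other.site
            ):
                value += self.pair_terms[pair]
        # deterministic model: replicates are identical, sd exactly 0
        return DdgEstimate(float(value), 0.0, self.n_runs)


class TableDdgPredictor:
    """ddG lookup from a CSV of externally computed values.

    The CSV needs columns ``mutation_name,ddg`` and may carry an
    optional ``run`` column; rows sharing a mutation name are aggregated
    into mean and (population) standard deviation.  Context-independent
    by construction.
    """

    def __init__(self, table: Mapping[str, DdgEstimate]):
        self._table = dict(table)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TableDdgPredictor":
        df = pd.read_csv(path)
        missing = {"mutation_name", "ddg"} - set(df.columns)
        if missing:
            raise ValueError(f"ddG table lacks columns {sorted(missing)}")
        table = {}
        for name, group in df.groupby("mutation_name", sort=False):
            values = group["ddg"].to_numpy(dtype=float)
            table[str(name)] = DdgEstimate(
                mean=float(values.mean()),
                sd=float(values.std()) if len(values) > 1 else 0.0,
                n_runs=len(values),
            )
        return cls(table)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"mutation_name": name, "ddg": est.mean + offset}
            for name, est in sorted(self._table.items())
            for offset in _replicate_offsets(est)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    def ddg(self, mutation, context: Iterable = ()) -> DdgEstimate:
        name = mutation if isinstance(mutation, str) else mutation.name
        try:
            return self._table[name]
        except KeyError:
            raise KeyError(f"no ddG value for mutation {name!r} in table") from None


def _replicate_offsets(est: DdgEstimate) -> np.ndarray:
    """Offsets reconstructing n replicates with the stored mean and sd."""
    if est.n_runs == 1 or est.sd == 0.0:
        return np.zeros(est.n_runs)
    if est.n_runs == 2:
        return np.array([-est.sd, est.sd])
    # three-point symmetric design: {-s*sqrt(3/2), 0, +s*sqrt(3/2)} padded
    out = np.zeros(est.n_runs)
    spread = est.sd * np.sqrt(est.n_runs / 2.0)
    out[0], out[-1] = -spread, spread
    return out
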