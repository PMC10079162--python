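"""Transparent per-residue solubility model.

The model follows the structure of profile-based aggregation/solubility
predictors: a raw physicochemical score per residue (hydropathy, net
charge, beta-sheet propensity), locally averaged along the sequence into
an intrinsic profile, optionally reweighted by solvent exposure and 3-D
neighbourhood into a structurally corrected profile, and condensed into
one global score per sequence set.  Higher values mean more soluble.
Coefficients are declared package constants, not fitted; the pipeline
contract only requires a deterministic, monotone solubility functional,
and externally computed scores can be substituted through the CSV
import below.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import BETA_PROPENSITY_Z, CHARGE, HYDROPATHY_Z
from .structure import ContactMap, ProteinStructure, ResidueKey


@dataclass
class SeqMutation:
    """A substitution located by chain id and 0-based sequence index."""

    chain: str
    index: int
    wt: str
    mut: str


@dataclass
class SolubilityProfile:
    intrinsic: dict[str, np.ndarray]  # chain id -> per-residue values
    corrected: dict[ResidueKey, float]
    global_score: float


class SolubilityModel:
    """Sequence- and structure-based solubility scoring.

    Parameters
    ----------
    w_hydropathy, w_charge, w_beta:
        Weights of the (negated, z-scored) hydropathy, absolute net
        charge, and (negated, z-scored) beta-propensity contributions to
        the raw residue score.
    window:
        Length of the local averaging window (truncated at termini).
    penalty_threshold:
        Profile level below which residues are counted as poorly
        soluble in the global score's penalty term.
    """

    def __init__(
        self,
        w_hydropathy: float = 1.0,
        w_charge: float = 0.5,
        w_beta: float = 0.5,
        window: int = 7,
        penalty_threshold: float = -1.0,
    ):
        self.w_hydropathy = w_hydropathy
        self.w_charge = w_charge
        self.w_beta = w_beta
        self.window = int(window)
        self.penalty_threshold = penalty_threshold

    def residue_score(self, aa: str) -> float:
        """Raw (pre-smoothing) solubility score of one amino acid."""
        if aa not in HYDROPATHY_Z:
            return 0.0  # unknown residue type is neutral
        return (
            self.w_hydropathy * (-HYDROPATHY_Z[aa])
            + self.w_charge * abs(CHARGE.get(aa, 0.0))
            + self.w_beta * (-BETA_PROPENSITY_Z[aa])
        )

    def intrinsic_profile(self, sequence: str) -> np.ndarray:
        """Window-averaged per-residue solubility profile."""
        if not sequence:
            raise ValueError("empty sequence")
        raw = np.array([self.residue_score(aa) for aa in sequence])
        half = self.window // 2
        profile = np.empty_like(raw)
        for i in range(len(raw)):
            lo, hi = max(0, i - half), min(len(raw), i + half + 1)
            profile[i] = raw[lo:hi].mean()
        return profile

    def global_score(self, sequences: str | Sequence[str]) -> float:
        """One solubility number for a sequence or a multi-chain complex.

        Mean of the concatenated intrinsic profiles minus the mean
        depth by which profile values fall below the penalty threshold.
        """
        if isinstance(sequences, str):
            sequences = [sequences]
        profiles = [self.intrinsic_profile(s) for s in sequences]
        p = np.concatenate(profiles)
        penalty = np.maximum(0.0, self.penalty_threshold - p).sum() / len(p)
        return float(p.mean() - penalty)

    def structural_profile(
        self,
        structure: ProteinStructure,
        exposure: Mapping[ResidueKey, float],
        contacts: ContactMap,
        intrinsic: Mapping[str, np.ndarray],
    ) -> dict[ResidueKey, float]:
        """Exposure-weighted neighbourhood average of the intrinsic profile.

        Buried residues score near zero; low-scoring exposed residues
        mark surface aggregation hotspots.
        """
        values: dict[ResidueKey, float] = {}
        for chain in structure.chains:
            idx = chain.seq_index_map()
            for res in chain.residues:
                key = res.key(chain.id)
                if key not in exposure:
                    continue
                values[key] = float(intrinsic[chain.id][idx[key]])

        corrected: dict[ResidueKey, float] = {}
        for key, own in values.items():
            nbrs = [k for k in contacts.neighbours(key) if k in values]
            total = own + sum(values[k] for k in nbrs)
            corrected[key] = exposure[key] * total / (1 + len(nbrs))
        return corrected

    def mutate_chains(
        self,
        wt_chains: Mapping[str, str],
        mutations: Iterable[SeqMutation],
        identity_groups: Sequence[Sequence[str]],
    ) -> dict[str, str]:
        """Apply mutations, mirroring each across its identity group."""
        seqs = {cid: list(seq) for cid, seq in wt_chains.items()}
        group_of = {cid: tuple(g) for g in identity_groups for cid in g}
        for m in mutations:
            for cid in group_of.get(m.chain, (m.chain,)):
                if cid not in seqs:
                    continue
                if seqs[cid][m.index] != m.wt:
                    raise ValueError(
                        f"mutation {m.wt}{m.chain}{m.index + 1}{m.mut}: "
                        f"sequence of chain {cid} has "
                        f"{seqs[cid][m.index]!r} at that site"
                    )
                seqs[cid][m.index] = m.mut
        return {cid: "".join(s) for cid, s in seqs.items()}

    def delta_solubility(
        self,
        wt_chains: Mapping[str, str],
        mutations: Iterable[SeqMutation],
        identity_groups: Sequence[Sequence[str]],
    ) -> float:
        """Global-score change of a mutation set (mutant minus wild type)."""
        mutant = self.mutate_chains(wt_chains, mutations, identity_groups)
        order = list(wt_chains)
        return self.global_score([mutant[c] for c in order]) - self.global_score(
            [wt_chains[c] for c in order]
        )


def export_profiles_csv(
    path: str | Path,
    structure: ProteinStructure,
    intrinsic: Mapping[str, np.ndarray],
    corrected: Mapping[ResidueKey, float],
) -> None:
    rows = []
    for chain in structure.chains:
        idx = chain.seq_index_map()
        for res in chain.residues:
            key = res.key(chain.id)
            rows.append(
                {
                    "chain": chain.id,
                    "resnum": res.number,
                    "icode": res.icode or "",
                    "aa": res.aa,
                    "intrinsic": float(intrinsic[chain.id][idx[key]]),
                    "corrected": corrected.get(key, np.nan),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


class ExternalSolubility:
    """Per-residue and global solubility scores imported from CSV.

    Expected columns: ``chain,resnum,value`` plus one row with
    ``chain == 'GLOBAL'`` carrying the global score.  Lets an external
    solubility predictor stand in for the bundled model bit-for-bit.
    """

    def __init__(self, per_residue: dict[tuple[str, int], float], global_score: float):
        self.per_residue = per_residue
        self.global_score = global_score

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExternalSolubility":
        df = pd.read_csv(path)
        global_rows = df[df["chain"] == "GLOBAL"]
        if len(global_rows) != 1:
            raise ValueError("external solubility CSV needs exactly one GLOBAL row")
        per_residue = {
            (str(r.chain), int(r.resnum)): float(r.value)
            for r in df[df["chain"] != "GLOBAL"].itertuples()
        }
        return cls(per_residue, float(global_rows["value"].iloc[0]))
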