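"""Deterministic synthetic inputs for every pipeline stage.

Three generators cover the pipeline's input formats without any
external downloads: ideal alpha-helix PDB files (backbone + C-beta,
standard bond geometry, phi = -57 deg, psi = -47 deg), column-controlled
multiple sequence alignments, and stratified synthetic ddG benchmark
tables whose strata have known false-discovery rates.  All generators
are pure functions of their arguments; the same arguments always yield
byte-identical output.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .benchmark import BenchmarkRecord
from .data import AMINO_ACIDS
from .phylo import Msa
from .structure import Atom, Chain, ProteinStructure, Residue, write_pdb

# backbone internal coordinates (Engh & Huber style ideal values)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_BOND_CA_CB = 1.530
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8
_ANGLE_N_CA_CB = 110.5
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d with |cd| = bond, angle(b,c,d), torsion(a,b,c,d)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _helix_coordinates(length: int) -> list[dict[str, np.ndarray]]:
    """Backbone N, CA, C, O and CB positions of an ideal alpha helix."""
    residues: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BOND_N_CA, 0.0, 0.0])
    dummy = np.array([0.0, 1.0, 0.0])
    c = _place(dummy, n, ca, _BOND_CA_C, _ANGLE_N_CA_C, 60.0)
    residues.append({"N": n, "CA": ca, "C": c})
    for _ in range(1, length):
        n_next = _place(n, ca, c, _BOND_C_N, _ANGLE_CA_C_N, _PSI)
        ca_next = _place(ca, c, n_next, _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA)
        c_next = _place(c, n_next, ca_next, _BOND_CA_C, _ANGLE_N_CA_C, _PHI)
        residues.append({"N": n_next, "CA": ca_next, "C": c_next})
        n, ca, c = n_next, ca_next, c_next
    for res in residues:
        res["O"] = _place(res["N"], res["CA"], res["C"], _BOND_C_O,
                          _ANGLE_CA_C_O, _PSI + 180.0)
        res["CB"] = _place(res["C"], res["N"], res["CA"], _BOND_CA_CB,
                           _ANGLE_N_CA_CB, 122.6)
    return residues


def make_helix_structure(
    sequences: Mapping[str, str],
    offsets: Optional[Mapping[str, Sequence[float]]] = None,
) -> ProteinStructure:
    """Ideal alpha-helix structure, one rigidly offset helix per chain.

    Chains are translated by ``offsets`` (default: 30 Angstrom apart
    along x, i.e. non-contacting) so inter-chain minimum distances are
    controllable.  Glycines carry no C-beta.
    """
    chains = []
    for i, (cid, seq) in enumerate(sequences.items()):
        if not seq:
            raise ValueError(f"chain {cid}: empty sequence")
        offset = np.asarray(
            offsets[cid] if offsets and cid in offsets else [30.0 * i, 0.0, 0.0],
            dtype=float,
        )
        coords = _helix_coordinates(len(seq))
        residues = []
        for num, (aa, pos) in enumerate(zip(seq, coords), start=1):
            names = ["N", "CA", "C", "O"] + ([] if aa == "G" else ["CB"])
            atoms = [
                Atom(name, name[0], np.round(pos[name] + offset, 3))
                for name in names
            ]
            residues.append(Residue(num, None, aa, atoms))
        chains.append(Chain(cid, seq, residues))
    return ProteinStructure(chains)


def make_helix_pdb(
    sequences: Mapping[str, str],
    offsets: Optional[Mapping[str, Sequence[float]]] = None,
    path: Optional[str | Path] = None,
) -> str:
    """PDB text (SEQRES + ATOM records) of :func:`make_helix_structure`."""
    return write_pdb(make_helix_structure(sequences, offsets), path)


def make_msa(
    master: str,
    n_sequences: int,
    consensus_fraction: float | Sequence[float] = 0.9,
    seed: int = 0,
    alphabet: str = AMINO_ACIDS,
    column_distributions: Optional[Mapping[int, Mapping[str, float]]] = None,
) -> Msa:
    """Sample an alignment with a controlled per-column composition.

    By default each row keeps the master letter at column ``j`` with
    probability ``consensus_fraction[j]`` and otherwise draws uniformly
    from the remaining letters of ``alphabet``.  ``column_distributions``
    overrides individual (0-based) columns with an explicit categorical
    distribution over amino acids; residual probability mass is spread
    uniformly over the unmentioned letters.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    L = len(master)
    fractions = np.broadcast_to(
        np.asarray(consensus_fraction, dtype=float), (L,)
    ).copy()
    if ((fractions < 0) | (fractions > 1)).any():
        raise ValueError("consensus fractions must lie in [0, 1]")

    probs = np.zeros((L, len(alphabet)))
    letter_index = {a: i for i, a in enumerate(alphabet)}
    for j, wt in enumerate(master):
        dist = (column_distributions or {}).get(j)
        if dist is None:
            c = fractions[j]
            probs[j, :] = (1.0 - c) / (len(alphabet) - 1)
            probs[j, letter_index[wt]] = c
        else:
            total = sum(dist.values())
            if total > 1.0 + 1e-9 or any(p < 0 for p in dist.values()):
                raise ValueError(f"invalid column distribution at {j}")
            rest = [a for a in alphabet if a not in dist]
            for a, p in dist.items():
                probs[j, letter_index[a]] = p
            if rest:
                probs[j, [letter_index[a] for a in rest]] = (1.0 - total) / len(rest)

    rng = np.random.default_rng(seed)
    draws = np.array(
        [rng.choice(len(alphabet), size=n_sequences, p=probs[j]) for j in range(L)]
    ).T
    rows = ["".join(alphabet[k] for k in row) for row in draws]
    return Msa(master_sequence=master, rows=rows)


def write_msa_fasta(msa: Msa, path: str | Path) -> None:
    """Write an alignment as aligned FASTA (first row = master)."""
    with open(path, "w") as fh:
        fh.write(f">master\n{msa.master_sequence}\n")
        for i, row in enumerate(msa.rows):
            if i == 0 and row == msa.master_sequence:
                continue
            fh.write(f">seq{i}\n{row}\n")


# Demo design target: a 35-residue helix combining an aggregation-prone
# hydrophobic patch (V/L/I stretch, columns enriched in glutamate among
# homologs) with several exposed Arg/His positions whose homolog columns
# are enriched in lysine.  The Lys substitutions gain both solubility and
# (mildly) stability under the bundled surrogates, so the full pipeline
# produces non-trivial designs; the patch positions are proposed but
# rejected at the stability filter, exercising the drop reasons.
DEMO_SEQUENCE = "MKTAYIAKQRELHAEGRVLIVLSREAHKAWRETNK"
_KCOLS = (9, 12, 16, 23, 26, 30)  # 0-based Arg/His positions (R/H -> K)
_ECOLS = (17, 18, 19, 20, 21)  # hydrophobic patch (-> E among homologs)
DEMO_COLUMN_MODEL: dict[int, dict[str, float]] = {
    **{j: {"K": 0.55, DEMO_SEQUENCE[j]: 0.25} for j in _KCOLS},
    **{j: {"E": 0.50, DEMO_SEQUENCE[j]: 0.30} for j in _ECOLS},
    # a conserved column where the wild type (T33) is rare among homologs
    32: {"A": 0.85, "T": 0.03},
}


def make_design_fixture(
    n_sequences: int = 80,
    seed: int = 0,
    n_chains: int = 1,
) -> tuple[ProteinStructure, Msa]:
    """Structure + alignment demo pair driving the full design pipeline.

    With ``n_chains=2`` the second chain is an identical, well-separated
    copy (a homodimer), exercising identity-group propagation.
    """
    chains = {chr(ord("A") + i): DEMO_SEQUENCE for i in range(n_chains)}
    structure = make_helix_structure(chains)
    msa = make_msa(
        DEMO_SEQUENCE,
        n_sequences,
        consensus_fraction=0.85,
        seed=seed,
        column_distributions=DEMO_COLUMN_MODEL,
    )
    return structure, msa


def make_ddg_benchmark(
    n: int = 2000,
    fdr_pos_ll: float = 0.15,
    fdr_nonpos_ll: float = 0.45,
    frac_pos_ll: float = 0.5,
    frac_pred_stab: float = 0.5,
    seed: int = 0,
) -> list[BenchmarkRecord]:
    """Stratified synthetic benchmark with known per-stratum FDRs.

    Records split into a positive-delta-log-likelihood stratum
    (``frac_pos_ll`` of records, FDR ``fdr_pos_ll`` among its predicted
    stabilising mutations) and a complement stratum with FDR
    ``fdr_nonpos_ll``.  With the 0.15 / 0.45 defaults and equal strata
    the overall expected FDR is 0.30.  Half of the complement stratum
    still has ``loglik_mut > 0`` so the two phylogenetic filters are
    strictly nested.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for p in (fdr_pos_ll, fdr_nonpos_ll, frac_pos_ll, frac_pred_stab):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    aas = AMINO_ACIDS
    for i in range(n):
        pos_stratum = rng.random() < frac_pos_ll
        fdr = fdr_pos_ll if pos_stratum else fdr_nonpos_ll
        mag_pred = abs(rng.normal(1.0, 0.5)) + 0.05
        mag_exp = abs(rng.normal(1.0, 0.5)) + 0.05
        if rng.random() < frac_pred_stab:
            ddg_pred = -mag_pred
            ddg_exp = mag_exp if rng.random() < fdr else -mag_exp
        else:
            ddg_pred = mag_pred
            ddg_exp = mag_exp if rng.random() < 0.5 else -mag_exp
        if pos_stratum:
            delta_ll = rng.uniform(0.05, 2.0)
            loglik = rng.uniform(0.05, 2.0)
        else:
            delta_ll = rng.uniform(-2.0, 0.0)
            loglik = (
                rng.uniform(0.05, 2.0) if rng.random() < 0.5
                else rng.uniform(-2.0, -0.05)
            )
        wt = aas[rng.integers(20)]
        mut = aas[rng.integers(20)]
        while mut == wt:
            mut = aas[rng.integers(20)]
        records.append(
            BenchmarkRecord(
                protein_id=f"P{i % 20:02d}",
                mutation=f"{wt}A{i + 1}{mut}",
                ddg_exp=float(ddg_exp),
                ddg_pred=float(ddg_pred),
                loglik_mut=float(loglik),
                delta_loglik=float(delta_ll),
            )
        )
    return records
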