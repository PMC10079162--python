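"""Mutation-design pipeline: sites, single scan, combinations, shortlist.

The design loop proposes mutations that simultaneously improve
solubility and conformational stability:

1. candidate sites are picked from the solubility profiles, from
   conservation, and from exposed positions with solubilising options;
2. every PSSM-permitted substitution is scanned singly and filtered
   (solubility gain, stabilising ddG, no excluded target residues);
3. survivors are combined into multi-mutation designs, with additive
   ddG / phylogeny scores and recomputed solubility;
4. design groups (one per total mutation count) are ranked by the
   Mutation Score, a knee rule picks the best trade-off groups, and a
   shortlist is emitted;
5. designs whose sites touch in the structure are re-evaluated
   sequentially with a context-aware predictor, replacing or removing
   mutations that turn destabilising in context.

Mutations on a chain are always mirrored across its identity group
(identical chains are encoded by the same gene), so a "logical site"
lives on the group's representative chain and the ddG is multiplied by
the group size.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .phylo import Pssm, allowed_substitutions
from .solubility import SeqMutation, SolubilityModel
from .stability import DdgEstimate, propagate_multiplicity
from .structure import ContactMap, ProteinStructure, ResidueKey


# ---------------------------------------------------------------------------
# mutation naming


@dataclass(frozen=True)
class Mutation:
    """A named single substitution at a structure residue."""

    wt: str
    chain: str
    number: int
    icode: Optional[str]
    mut: str

    @property
    def site(self) -> ResidueKey:
        return (self.chain, self.number, self.icode)

    @property
    def name(self) -> str:
        return f"{self.wt}{self.chain}{self.number}{self.icode or ''}{self.mut}"

    def __str__(self) -> str:
        return self.name


_MUTATION_RE = re.compile(
    r"^(?P<wt>[A-Z])(?P<chain>[A-Za-z0-9])(?P<number>-?\d+)"
    r"(?P<icode>[A-Za-z]?)(?P<mut>[A-Z])$"
)


def format_mutation(
    wt: str, chain: str, number: int, icode: Optional[str], mut: str
) -> str:
    """Canonical mutation name, e.g. ``LA24D`` for Leu24Asp on chain A."""
    return Mutation(wt, chain, number, icode, mut).name


def parse_mutation(name: str) -> Mutation:
    """Invert :func:`format_mutation`."""
    m = _MUTATION_RE.match(name.strip())
    if not m:
        raise ValueError(f"cannot parse mutation name {name!r}")
    return Mutation(
        wt=m.group("wt"),
        chain=m.group("chain"),
        number=int(m.group("number")),
        icode=m.group("icode") or None,
        mut=m.group("mut"),
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class DesignConfig:
    """Thresholds and exclusions steering the design pipeline."""

    exposure_threshold: float = 0.10  # minimum relative exposure = "exposed"
    theta_seq: float = -1.0  # intrinsic-profile hotspot threshold
    theta_str: float = -0.5  # corrected-profile hotspot threshold
    ci_min: float = 0.25  # minimum conservation for conservation sites
    ci_consensus: float = 0.7  # consensus guard for exposed-solubility sites
    max_sites: int = 100
    pssm_mode: str = "ll_and_delta"  # or "ll_pos"
    excluded_targets: frozenset = frozenset({"C", "M"})
    excluded_chains: frozenset = frozenset()
    excluded_positions: frozenset = frozenset()  # of ResidueKey
    antigen_chains: frozenset = frozenset()
    max_mutations: int = 5
    w_solubility: float = 1.0
    w_stability: float = 1.0
    w_phylogeny: float = 1.0
    contact_cutoff: float = 8.0
    antigen_contact_cutoff: float = 4.5
    max_group_designs: int = 20000  # exact enumeration bound per group
    beam_width: int = 500  # fallback recursive beam for huge spaces


# ---------------------------------------------------------------------------
# candidate sites

CATEGORY_ORDER = (
    "sequence_solubility",
    "structure_solubility",
    "conservation",
    "exposed_solubility",
    "custom",
)


@dataclass
class CandidateSite:
    chain: str
    number: int
    icode: Optional[str]
    wt: str
    exposure: float
    seq_index: int  # position in the chain's comparison sequence / PSSM
    categories: set[str] = field(default_factory=set)

    @property
    def key(self) -> ResidueKey:
        return (self.chain, self.number, self.icode)


@dataclass
class DesignContext:
    """Precomputed inputs shared by the pipeline stages."""

    structure: ProteinStructure
    identity_groups: Sequence[tuple[str, ...]]
    pssms: Mapping[str, Pssm]  # keyed by representative chain id
    exposure: Mapping[ResidueKey, float]
    contacts: ContactMap
    solubility: SolubilityModel
    intrinsic: Mapping[str, np.ndarray]
    corrected: Mapping[ResidueKey, float]
    config: DesignConfig

    @property
    def wt_chains(self) -> dict[str, str]:
        return {c.id: c.comparison_sequence for c in self.structure.chains}

    def group_of(self, chain_id: str) -> tuple[str, ...]:
        for g in self.identity_groups:
            if chain_id in g:
                return tuple(g)
        return (chain_id,)

    def representative_chains(self) -> list[str]:
        """First chain of each identity group, minus exclusions."""
        excluded = set(self.config.excluded_chains) | set(self.config.antigen_chains)
        reps = []
        for group in self.identity_groups:
            designable = [c for c in group if c not in excluded]
            if designable:
                reps.append(designable[0])
        return reps

    def seq_mutation(self, mutation: Mutation) -> SeqMutation:
        chain = self.structure.chain(mutation.chain)
        idx = chain.seq_index_map()[mutation.site]
        return SeqMutation(mutation.chain, idx, mutation.wt, mutation.mut)

    def delta_solubility(self, mutations: Iterable[Mutation]) -> float:
        return self.solubility.delta_solubility(
            self.wt_chains,
            [self.seq_mutation(m) for m in mutations],
            self.identity_groups,
        )


def select_sites(
    ctx: DesignContext,
    custom_sites: Iterable[ResidueKey] = (),
) -> list[CandidateSite]:
    """Identify candidate mutation sites on the representative chains.

    Categories: poorly soluble and exposed in sequence space
    (``sequence_solubility``); member of a surface hotspot patch in the
    corrected profile (``structure_solubility``); conserved position
    with a rare wild type (``conservation``, no exposure requirement);
    exposed position with a solubilising permitted substitution
    (``exposed_solubility``, unless highly conserved with the wild type
    already the consensus).  Exposed-solubility sites are discarded when
    the first three categories already reach the site cap, otherwise
    added by decreasing best solubility gain until the cap is reached.
    """
    cfg = ctx.config
    sites: dict[ResidueKey, CandidateSite] = {}
    cat4: list[tuple[float, CandidateSite]] = []

    for cid in ctx.representative_chains():
        chain = ctx.structure.chain(cid)
        pssm = ctx.pssms[cid]
        idx_map = chain.seq_index_map()
        profile = ctx.intrinsic[cid]
        for res in chain.residues:
            key = res.key(cid)
            if res.aa not in "ACDEFGHIKLMNPQRSTVWY":
                continue
            if key in cfg.excluded_positions:
                continue
            j = idx_map[key]
            exp = float(ctx.exposure.get(key, 0.0))
            cats: set[str] = set()
            if profile[j] < cfg.theta_seq and exp >= cfg.exposure_threshold:
                cats.add("sequence_solubility")
            if ctx.corrected.get(key, 0.0) < cfg.theta_str:
                cats.add("structure_solubility")
            if pssm.conservation[j] > cfg.ci_min and pssm.wt_low(j, res.aa):
                cats.add("conservation")

            site = CandidateSite(
                cid, res.number, res.icode, res.aa, exp, j, set(cats)
            )

            # exposed-solubility: a permitted substitution must gain solubility
            consensus_guard = (
                pssm.conservation[j] > cfg.ci_consensus
                and pssm.consensus(j) == res.aa
            )
            if exp >= cfg.exposure_threshold and not consensus_guard:
                best_gain = -math.inf
                allowed = allowed_substitutions(pssm, j, res.aa, cfg.pssm_mode)
                for mut in sorted(allowed - set(cfg.excluded_targets)):
                    gain = ctx.delta_solubility(
                        [Mutation(res.aa, cid, res.number, res.icode, mut)]
                    )
                    best_gain = max(best_gain, gain)
                if best_gain > 0:
                    site.categories.add("exposed_solubility")
                    if not cats:
                        cat4.append((best_gain, site))
            if cats:
                sites[key] = site

    n_core = len(sites)
    if n_core < cfg.max_sites:
        cat4.sort(key=lambda t: (-t[0], t[1].chain, t[1].number, t[1].icode or ""))
        for _, site in cat4:
            if len(sites) >= cfg.max_sites:
                break
            sites[site.key] = site
    # n_core >= cap: exposed-solubility-only sites are discarded entirely

    for key in custom_sites:
        res = ctx.structure.residue(key)  # raises KeyError if absent
        if key in sites:
            sites[key].categories.add("custom")
        else:
            chain = ctx.structure.chain(key[0])
            j = chain.seq_index_map()[key]
            sites[key] = CandidateSite(
                key[0], key[1], key[2], res.aa,
                float(ctx.exposure.get(key, 0.0)), j, {"custom"},
            )

    order = {cid: i for i, cid in enumerate(ctx.structure.chain_ids)}
    return sorted(
        sites.values(), key=lambda s: (order[s.chain], s.number, s.icode or "")
    )


# ---------------------------------------------------------------------------
# single mutational scanning


@dataclass
class ScanAttempt:
    """One attempted substitution with its scores and fate."""

    mutation: Mutation
    categories: set[str]
    delta_solubility: Optional[float] = None
    ddg: Optional[DdgEstimate] = None
    delta_loglik: Optional[float] = None
    drop_reason: Optional[str] = None  # None = survived


@dataclass
class MutationRecord:
    """A surviving single mutation with all pipeline scores."""

    mutation: Mutation
    site: CandidateSite
    delta_solubility: float
    ddg: DdgEstimate
    delta_loglik: float
    delta_loglik_norm: float = 0.0
    mutation_score: float = 0.0

    @property
    def name(self) -> str:
        return self.mutation.name


def mutation_score(
    delta_solubility: float,
    ddg_propagated: float,
    delta_loglik_norm: float,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """Combined ranking score: solubility gain, stability gain, phylogeny.

    ``MS = w_s * dSol - w_g * ddG + w_p * dLL_norm`` — larger is better
    (stabilising ddG values are negative, hence the minus sign).
    """
    w_s, w_g, w_p = weights
    return w_s * delta_solubility - w_g * ddg_propagated + w_p * delta_loglik_norm


def normalize_delta_loglik(
    records: Sequence[MutationRecord], pssms: Mapping[str, Pssm]
) -> None:
    """Divide each record's score change by its chain PSSM's overall sd.

    Makes phylogenetic gains comparable across chains whose alignments
    have different depths.  A degenerate (constant) matrix normalises
    to zero.
    """
    for rec in records:
        sd = pssms[rec.mutation.chain].sd
        rec.delta_loglik_norm = rec.delta_loglik / sd if sd > 1e-12 else 0.0


def single_scan(
    ctx: DesignContext,
    sites: Sequence[CandidateSite],
    predictor,
) -> tuple[list[ScanAttempt], list[MutationRecord]]:
    """Scan every permitted substitution at every candidate site.

    Filters, in order: excluded target residues; solubility loss
    (waived at buried conservation sites); non-stabilising propagated
    ddG.  Returns the full attempts table and the surviving records
    with normalised phylogeny scores and Mutation Scores.
    """
    cfg = ctx.config
    attempts: list[ScanAttempt] = []
    records: list[MutationRecord] = []
    for site in sites:
        pssm = ctx.pssms[site.chain]
        allowed = allowed_substitutions(pssm, site.seq_index, site.wt, cfg.pssm_mode)
        group_size = len(ctx.group_of(site.chain))
        for mut in sorted(allowed):
            mutation = Mutation(site.wt, site.chain, site.number, site.icode, mut)
            attempt = ScanAttempt(mutation, set(site.categories))
            attempts.append(attempt)
            if mut in cfg.excluded_targets:
                attempt.drop_reason = "excluded_target"
                continue
            dsol = ctx.delta_solubility([mutation])
            attempt.delta_solubility = dsol
            buried_conservation = (
                "conservation" in site.categories
                and site.exposure < cfg.exposure_threshold
            )
            if dsol < 0 and not buried_conservation:
                attempt.drop_reason = "delta_solubility"
                continue
            est = propagate_multiplicity(predictor.ddg(mutation, ()), group_size)
            attempt.ddg = est
            if est.propagated >= 0:
                attempt.drop_reason = "ddg"
                continue
            dll = pssm.delta_loglik(site.seq_index, site.wt, mut)
            attempt.delta_loglik = dll
            records.append(
                MutationRecord(mutation, site, dsol, est, dll)
            )
    normalize_delta_loglik(records, ctx.pssms)
    weights = (cfg.w_solubility, cfg.w_stability, cfg.w_phylogeny)
    for rec in records:
        rec.mutation_score = mutation_score(
            rec.delta_solubility, rec.ddg.propagated, rec.delta_loglik_norm, weights
        )
    return attempts, records


# ---------------------------------------------------------------------------
# combining mutations


@dataclass
class Design:
    """A combination of mutations (at most one per logical site)."""

    mutations: tuple[Mutation, ...]
    delta_solubility: float
    ddg_sum: float
    delta_loglik_norm_sum: float
    mutation_score: float
    potentially_interacting: bool = False
    checked: bool = False

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.mutations)


def _rank_key(d: Design):
    # ties: lower ddG first, then higher solubility gain, then name
    return (-d.mutation_score, d.ddg_sum, -d.delta_solubility, d.names)


def rank_designs(designs: Iterable[Design]) -> list[Design]:
    return sorted(designs, key=_rank_key)


def _sites_interact(sites: Sequence[ResidueKey], contacts: ContactMap) -> bool:
    return any(
        contacts.in_contact(a, b) for a, b in itertools.combinations(sites, 2)
    )


def _make_design(
    ctx: DesignContext,
    members: Sequence[MutationRecord],
    weights: tuple[float, float, float],
) -> Design:
    mutations = tuple(m.mutation for m in members)
    dsol = ctx.delta_solubility(mutations)
    ddg_sum = sum(m.ddg.propagated for m in members)
    dll_sum = sum(m.delta_loglik_norm for m in members)
    return Design(
        mutations=mutations,
        delta_solubility=dsol,
        ddg_sum=ddg_sum,
        delta_loglik_norm_sum=dll_sum,
        mutation_score=mutation_score(dsol, ddg_sum, dll_sum, weights),
        potentially_interacting=_sites_interact(
            [m.mutation.site for m in members], ctx.contacts
        ),
    )


def combine(
    ctx: DesignContext,
    records: Sequence[MutationRecord],
    max_mutations: Optional[int] = None,
) -> dict[int, list[Design]]:
    """Build ranked design groups for n = 1 .. max_mutations.

    Singles with a negative Mutation Score are discarded first.  Pairs
    enumerate all site-disjoint combinations of surviving singles; from
    triples onward only the top-scoring substitution per site is used.
    ddG and normalised phylogeny scores are additive; the solubility
    change is recomputed on the fully mutated sequences.  Groups larger
    than ``config.max_group_designs`` fall back to a deterministic
    beam extension of the previous group.
    """
    cfg = ctx.config
    if max_mutations is None:
        max_mutations = cfg.max_mutations
    if max_mutations < 1:
        raise ValueError("max_mutations must be >= 1")
    weights = (cfg.w_solubility, cfg.w_stability, cfg.w_phylogeny)

    survivors = [r for r in records if r.mutation_score >= 0]
    rec_rank = lambda r: (
        -r.mutation_score,
        r.ddg.propagated,
        -r.delta_solubility,
        r.name,
    )
    survivors.sort(key=rec_rank)
    if not survivors:
        return {}

    groups: dict[int, list[Design]] = {}
    groups[1] = rank_designs(
        Design(
            (r.mutation,),
            r.delta_solubility,
            r.ddg.propagated,
            r.delta_loglik_norm,
            r.mutation_score,
        )
        for r in survivors
    )

    by_site: dict[ResidueKey, list[MutationRecord]] = {}
    for r in survivors:
        by_site.setdefault(r.mutation.site, []).append(r)
    top_per_site = sorted((recs[0] for recs in by_site.values()), key=rec_rank)
    n_sites = len(by_site)

    for n in range(2, max_mutations + 1):
        if n > n_sites:
            break
        if n == 2:
            pool: Sequence[MutationRecord] = survivors
        else:
            pool = top_per_site
        n_combos = math.comb(len(pool), n)
        if n == 2:
            combos = (
                c
                for c in itertools.combinations(pool, 2)
                if c[0].mutation.site != c[1].mutation.site
            )
            designs = [_make_design(ctx, c, weights) for c in combos]
        elif n_combos <= cfg.max_group_designs:
            designs = [
                _make_design(ctx, c, weights)
                for c in itertools.combinations(pool, n)
            ]
        else:
            designs = _beam_extend(ctx, groups[n - 1], by_site, weights, cfg)
        if not designs:
            break
        groups[n] = rank_designs(designs)[: cfg.max_group_designs]
    return groups


def _beam_extend(ctx, previous, by_site, weights, cfg) -> list[Design]:
    """Extend the top designs of the previous group by one top-per-site
    mutation at an unused site (deterministic fallback for very large
    combinatorial spaces)."""
    seen: set[frozenset] = set()
    out: list[Design] = []
    for base in previous[: cfg.beam_width]:
        used = {m.site for m in base.mutations}
        base_records = [by_site[m.site][0] for m in base.mutations]
        for site, recs in by_site.items():
            if site in used:
                continue
            members = base_records + [recs[0]]
            key = frozenset(m.mutation.name for m in members)
            if key in seen:
                continue
            seen.add(key)
            out.append(_make_design(ctx, members, weights))
    return out


def select_best_groups(groups: Mapping[int, Sequence[Design]]) -> set[int]:
    """Pick group sizes where the per-mutation gain starts to flatten.

    With ``M(n)`` the top Mutation Score of group ``n`` and
    ``g(n) = M(n) - M(n-1)``, an interior ``n`` is selected when the
    next gain falls below the mean of the gains so far.  If no interior
    knee exists the largest group is the best trade-off; the largest
    group is also added when its own gain still exceeds the mean of the
    earlier gains (the score is still accelerating into it).
    """
    sizes = sorted(groups)
    if not sizes:
        raise ValueError("no design groups")
    scores = {n: groups[n][0].mutation_score for n in sizes}
    return knee_groups(scores)


def knee_groups(scores: Mapping[int, float]) -> set[int]:
    """Knee rule on top scores per group size (see select_best_groups)."""
    sizes = sorted(scores)
    N = sizes[-1]
    if len(sizes) == 1:
        return {N}
    gains = {n: scores[n] - scores[prev] for prev, n in zip(sizes, sizes[1:])}
    gain_sizes = sorted(gains)
    best: set[int] = set()
    for i, n in enumerate(sizes[1:-1], start=1):
        later = sizes[i + 1]
        prior = [gains[m] for m in gain_sizes if m <= n]
        if gains[later] < float(np.mean(prior)):
            best.add(n)
    prior_to_last = [gains[m] for m in gain_sizes if m < N]
    if not best:
        best = {N}
    elif prior_to_last and gains[N] > float(np.mean(prior_to_last)):
        best.add(N)
    return best


def final_shortlist(
    groups: Mapping[int, Sequence[Design]], best: set[int]
) -> list[tuple[int, int, Design]]:
    """Three top designs per best group, one per other group.

    Returns (group size, rank within group, design) tuples ordered by
    group size then rank, so at least one design per mutation count is
    always proposed.
    """
    out: list[tuple[int, int, Design]] = []
    for n in sorted(groups):
        take = 3 if n in best else 1
        for rank, design in enumerate(groups[n][:take], start=1):
            out.append((n, rank, design))
    return out


# ---------------------------------------------------------------------------
# interaction check


def interaction_check(
    ctx: DesignContext,
    design: Design,
    predictor,
    scan_records: Sequence[MutationRecord],
    max_alternatives: int = 3,
) -> Design:
    """Re-evaluate a potentially interacting design sequentially.

    Mutations are applied in descending single-score order, each scored
    in the context of those already applied.  A mutation whose
    in-context ddG turns non-stabilising is replaced by the best of up
    to three ranked alternatives at its site; with no viable
    alternative the site is dropped.  Scores are recomputed from the
    in-context ddG values and the design is marked checked.
    """
    if design.n_mutations < 2:
        raise ValueError("interaction check needs a design with >= 2 mutations")
    if not design.potentially_interacting:
        return design

    cfg = ctx.config
    weights = (cfg.w_solubility, cfg.w_stability, cfg.w_phylogeny)
    by_name = {r.name: r for r in scan_records}
    by_site: dict[ResidueKey, list[MutationRecord]] = {}
    for r in sorted(
        scan_records,
        key=lambda r: (-r.mutation_score, r.ddg.propagated, -r.delta_solubility, r.name),
    ):
        by_site.setdefault(r.mutation.site, []).append(r)

    ordered = sorted(
        design.mutations,
        key=lambda m: (-by_name[m.name].mutation_score, m.name),
    )
    kept: list[MutationRecord] = []
    context: list[Mutation] = []
    ddg_in_context: list[float] = []
    for m in ordered:
        record = by_name[m.name]
        group_size = len(ctx.group_of(m.chain))
        candidates = [record] + [
            alt for alt in by_site[m.site] if alt.name != m.name
        ][:max_alternatives]
        chosen = None
        chosen_ddg = None
        for cand in candidates:
            est = propagate_multiplicity(
                predictor.ddg(cand.mutation, tuple(context)), group_size
            )
            if est.propagated < 0:
                chosen, chosen_ddg = cand, est.propagated
                break
        if chosen is None:
            continue  # disruptive site removed
        kept.append(chosen)
        context.append(chosen.mutation)
        ddg_in_context.append(chosen_ddg)

    mutations = tuple(k.mutation for k in kept)
    if not mutations:
        return Design((), 0.0, 0.0, 0.0, 0.0, design.potentially_interacting, True)
    dsol = ctx.delta_solubility(mutations)
    ddg_sum = float(sum(ddg_in_context))
    dll_sum = sum(k.delta_loglik_norm for k in kept)
    return Design(
        mutations=mutations,
        delta_solubility=dsol,
        ddg_sum=ddg_sum,
        delta_loglik_norm_sum=dll_sum,
        mutation_score=mutation_score(dsol, ddg_sum, dll_sum, weights),
        potentially_interacting=design.potentially_interacting,
        checked=True,
    )


def resolve_group(
    ctx: DesignContext,
    group: Sequence[Design],
    predictor,
    scan_records: Sequence[MutationRecord],
    max_rounds: int = 3,
) -> tuple[Design, list[Design], list[Design]]:
    """Run the interaction check on a ranked group's top designs.

    Repeats on the new top design up to ``max_rounds`` times when a
    check lowers the leader's score.  Returns the best checked (or
    unflagged) design, the re-ranked group, and any checked designs
    whose mutation count changed (they compete in their new group).
    """
    working = list(group)
    reassigned: list[Design] = []
    n = working[0].n_mutations if working else 0
    for _ in range(max_rounds):
        if not working:
            break
        top = working[0]
        if not top.potentially_interacting or top.checked:
            break
        checked = interaction_check(ctx, top, predictor, scan_records)
        working.remove(top)
        if checked.n_mutations == n:
            working.append(checked)
        elif checked.n_mutations > 0:
            reassigned.append(checked)
        working = rank_designs(working)
        if working and working[0] is checked:
            break
    eligible = [d for d in working if d.checked or not d.potentially_interacting]
    best = eligible[0] if eligible else (working[0] if working else None)
    return best, working, reassigned


# ---------------------------------------------------------------------------
# antigen contacts


def flag_antigen_contacts(
    mutations: Iterable[Mutation],
    structure: ProteinStructure,
    antigen_chains: Iterable[str],
    cutoff: float = 4.5,
) -> dict[str, bool]:
    """Advisory flags: does a mutation's WT residue touch the antigen?

    A mutation is flagged when any heavy atom of its wild-type residue
    lies within ``cutoff`` of any heavy atom of an antigen chain.
    Flags never alter scores.
    """
    antigen_chains = set(antigen_chains)
    unknown = antigen_chains - set(structure.chain_ids)
    if unknown:
        raise ValueError(f"unknown antigen chain(s) {sorted(unknown)}")
    coords = []
    for cid in antigen_chains:
        for res in structure.chain(cid).residues:
            for atom in res.atoms:
                if atom.element.upper() != "H":
                    coords.append(atom.coord)
    antigen_xyz = np.asarray(coords, dtype=float)

    flags: dict[str, bool] = {}
    for m in mutations:
        res = structure.residue(m.site)
        res_xyz = np.asarray(
            [a.coord for a in res.atoms if a.element.upper() != "H"], dtype=float
        )
        if len(res_xyz) == 0 or len(antigen_xyz) == 0:
            flags[m.name] = False
            continue
        d2 = ((res_xyz[:, None, :] - antigen_xyz[None, :, :]) ** 2).sum(axis=2)
        flags[m.name] = bool((d2 <= cutoff**2).any())
    return flags
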