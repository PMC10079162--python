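"""End-to-end orchestration: configuration, the design run, and outputs.

:func:`run_design` executes the full pipeline — input processing, site
selection, single mutational scan, combination, shortlist, interaction
check — and writes CSV tables, mutant FASTA sequences, a markdown
report, the resolved configuration and a per-stage log into the output
directory.  Runs are deterministic: identical configuration and seed
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import designer as dz
from .designer import DesignConfig, DesignContext
from .phylo import build_pssm, read_msa
from .solubility import SolubilityModel, export_profiles_csv
from .stability import SurrogateDdgPredictor, TableDdgPredictor
from .structure import (
    ResidueKey,
    contact_map,
    identity_groups,
    read_structure,
    relative_exposure,
)

_POSITION_RE = re.compile(r"^(?P<chain>[A-Za-z0-9]):(?P<number>-?\d+)(?P<icode>[A-Za-z]?)$")


def parse_position(text: str) -> ResidueKey:
    """Parse ``"A:24"`` or ``"A:24B"`` into a residue key."""
    m = _POSITION_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse position {text!r} (expected CHAIN:NUMBER)")
    return (m.group("chain"), int(m.group("number")), m.group("icode") or None)


@dataclass
class RunConfig:
    """Everything a design run needs; mirrors the CLI flags."""

    structure_path: str
    msa_paths: dict = field(default_factory=dict)  # chain id -> path
    msa_path: Optional[str] = None  # single alignment for all chains
    ddg_table: Optional[str] = None  # CSV of external ddG values
    manual_identity_groups: Optional[list] = None  # list of chain-id lists
    excluded_chains: list = field(default_factory=list)
    excluded_positions: list = field(default_factory=list)  # "A:24" strings
    antigen_chains: list = field(default_factory=list)
    custom_sites: list = field(default_factory=list)  # "A:24" strings
    max_mutations: int = 5
    pssm_mode: str = "ll_and_delta"
    excluded_targets: list = field(default_factory=lambda: ["C", "M"])
    exposure_threshold: float = 0.10
    theta_seq: float = -1.0
    theta_str: float = -0.5
    ci_min: float = 0.25
    ci_consensus: float = 0.7
    max_sites: int = 100
    contact_cutoff: float = 8.0
    antigen_contact_cutoff: float = 4.5
    probe_radius: float = 1.4
    sphere_points: int = 256
    pseudocount: float = 1.0
    window: int = 7
    w_solubility: float = 1.0
    w_stability: float = 1.0
    w_phylogeny: float = 1.0
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def design_config(self) -> DesignConfig:
        return DesignConfig(
            exposure_threshold=self.exposure_threshold,
            theta_seq=self.theta_seq,
            theta_str=self.theta_str,
            ci_min=self.ci_min,
            ci_consensus=self.ci_consensus,
            max_sites=self.max_sites,
            pssm_mode=self.pssm_mode,
            excluded_targets=frozenset(self.excluded_targets),
            excluded_chains=frozenset(self.excluded_chains),
            excluded_positions=frozenset(
                parse_position(p) for p in self.excluded_positions
            ),
            antigen_chains=frozenset(self.antigen_chains),
            max_mutations=self.max_mutations,
            w_solubility=self.w_solubility,
            w_stability=self.w_stability,
            w_phylogeny=self.w_phylogeny,
            contact_cutoff=self.contact_cutoff,
            antigen_contact_cutoff=self.antigen_contact_cutoff,
        )


def make_context(
    structure,
    msas,
    cfg: Optional[DesignConfig] = None,
    manual_identity_groups=None,
    window: int = 7,
    probe: float = 1.4,
    sphere_points: int = 256,
    pseudocount: float = 1.0,
) -> DesignContext:
    """Assemble a :class:`DesignContext` from in-memory objects.

    ``msas`` is either one alignment applied to every designable
    identity group or a mapping from representative chain id to
    alignment.
    """
    cfg = cfg or DesignConfig()
    groups = identity_groups(structure, manual_identity_groups)
    solubility = SolubilityModel(window=window)
    intrinsic = {
        c.id: solubility.intrinsic_profile(c.comparison_sequence)
        for c in structure.chains
    }
    exposure = relative_exposure(structure, probe=probe, sphere_points=sphere_points)
    contacts = contact_map(structure, cutoff=cfg.contact_cutoff)
    corrected = solubility.structural_profile(structure, exposure, contacts, intrinsic)

    excluded = set(cfg.excluded_chains) | set(cfg.antigen_chains)
    pssms = {}
    for group in groups:
        designable = [c for c in group if c not in excluded]
        if not designable:
            continue
        rep = designable[0]
        msa = msas[rep] if isinstance(msas, dict) else msas
        if msa is None:
            raise ValueError(f"no alignment provided for designable chain {rep}")
        chain_len = len(structure.chain(rep).comparison_sequence)
        if len(msa.master_sequence) != chain_len:
            raise ValueError(
                f"alignment master length {len(msa.master_sequence)} does not "
                f"match chain {rep} sequence length {chain_len}"
            )
        pssms[rep] = build_pssm(msa, pseudocount=pseudocount)

    return DesignContext(
        structure=structure,
        identity_groups=groups,
        pssms=pssms,
        exposure=exposure,
        contacts=contacts,
        solubility=solubility,
        intrinsic=intrinsic,
        corrected=corrected,
        config=cfg,
    )


def build_context(config: RunConfig) -> tuple[DesignContext, object]:
    """Stage (i): read inputs and precompute shared quantities."""
    structure = read_structure(config.structure_path)
    if config.msa_paths:
        msas = {cid: read_msa(path) for cid, path in config.msa_paths.items()}
        if config.msa_path:
            default = read_msa(config.msa_path)
            msas = {**dict.fromkeys(structure.chain_ids, default), **msas}
    elif config.msa_path:
        msas = read_msa(config.msa_path)
    else:
        raise ValueError("no alignment provided (msa_path or msa_paths)")

    ctx = make_context(
        structure,
        msas,
        cfg=config.design_config(),
        manual_identity_groups=config.manual_identity_groups,
        window=config.window,
        probe=config.probe_radius,
        sphere_points=config.sphere_points,
        pseudocount=config.pseudocount,
    )
    if config.ddg_table:
        predictor = TableDdgPredictor.from_csv(config.ddg_table)
    else:
        predictor = SurrogateDdgPredictor(ctx.exposure, ctx.contacts)
    return ctx, predictor


def _sites_frame(ctx: DesignContext, sites) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chain": s.chain,
                "resnum": s.number,
                "icode": s.icode or "",
                "wt": s.wt,
                "exposure": round(s.exposure, 4),
                "conservation": round(
                    float(ctx.pssms[s.chain].conservation[s.seq_index]), 4
                ),
                "identified from": ";".join(
                    c for c in dz.CATEGORY_ORDER if c in s.categories
                ),
            }
            for s in sites
        ]
    )


def _attempts_frame(attempts) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mutation": a.mutation.name,
                "chain": a.mutation.chain,
                "resnum": a.mutation.number,
                "wt": a.mutation.wt,
                "mut": a.mutation.mut,
                "site categories": ";".join(
                    c for c in dz.CATEGORY_ORDER if c in a.categories
                ),
                "delta_solubility": _r(a.delta_solubility),
                "ddg": _r(a.ddg.mean if a.ddg else None),
                "ddg_propagated": _r(a.ddg.propagated if a.ddg else None),
                "delta_loglik": _r(a.delta_loglik),
                "status": a.drop_reason or "kept",
            }
            for a in attempts
        ]
    )


def _records_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mutation": r.name,
                "delta_solubility": _r(r.delta_solubility),
                "ddg": _r(r.ddg.mean),
                "ddg_sd": _r(r.ddg.sd),
                "ddg_propagated": _r(r.ddg.propagated),
                "delta_loglik": _r(r.delta_loglik),
                "delta_loglik_norm": _r(r.delta_loglik_norm),
                "mutation_score": _r(r.mutation_score),
            }
            for r in records
        ]
    )


def _design_row(n, rank, d, flags=None):
    row = {
        "n_mutations": n,
        "rank": rank,
        "mutations": "+".join(d.names),
        "delta_solubility": _r(d.delta_solubility),
        "ddg_sum": _r(d.ddg_sum),
        "delta_loglik_norm_sum": _r(d.delta_loglik_norm_sum),
        "mutation_score": _r(d.mutation_score),
        "potentially_interacting": d.potentially_interacting,
        "checked": d.checked,
    }
    if flags is not None:
        row["antigen_contact"] = "+".join(
            name for name in d.names if flags.get(name, False)
        )
    return row


def _r(x, nd: int = 6):
    return None if x is None else round(float(x), nd)


def run_design(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full design pipeline and write all outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    ctx, predictor = build_context(config)
    log.append(f"chains: {','.join(ctx.structure.chain_ids)}")
    log.append(
        "identity groups: "
        + " ".join("{" + ",".join(g) + "}" for g in ctx.identity_groups)
    )
    export_profiles_csv(outdir / "profiles.csv", ctx.structure, ctx.intrinsic,
                        ctx.corrected)

    custom = [parse_position(p) for p in config.custom_sites]
    sites = dz.select_sites(ctx, custom)
    log.append(f"candidate sites: {len(sites)}")
    _sites_frame(ctx, sites).to_csv(outdir / "sites.csv", index=False)

    attempts, records = dz.single_scan(ctx, sites, predictor)
    log.append(f"scan attempts: {len(attempts)}; survivors: {len(records)}")
    _attempts_frame(attempts).to_csv(outdir / "scan_attempts.csv", index=False)
    _records_frame(records).to_csv(outdir / "scan_shortlist.csv", index=False)

    groups = dz.combine(ctx, records)
    combo_rows = [
        _design_row(n, rank, d)
        for n in sorted(groups)
        for rank, d in enumerate(groups[n], start=1)
    ]
    pd.DataFrame(combo_rows).to_csv(outdir / "combinations.csv", index=False)
    log.append(
        "groups: "
        + " ".join(f"n={n}:{len(designs)}" for n, designs in sorted(groups.items()))
    )

    final_rows = []
    fasta_lines: list[str] = []
    if groups:
        best = dz.select_best_groups(groups)
        log.append(f"best groups: {sorted(best)}")
        resolved_groups = dict(groups)
        reassigned_all = []
        for n in sorted(groups):
            flagged_window = any(
                d.potentially_interacting for d in resolved_groups[n][:3]
            )
            if n >= 2 and flagged_window:
                _, reranked, reassigned = dz.resolve_group(
                    ctx, resolved_groups[n], predictor, records
                )
                resolved_groups[n] = reranked
                reassigned_all.extend(reassigned)
        for d in reassigned_all:
            m = d.n_mutations
            resolved_groups[m] = dz.rank_designs(list(resolved_groups.get(m, [])) + [d])

        shortlist = dz.final_shortlist(resolved_groups, best)
        antigen = sorted(ctx.config.antigen_chains)
        for n, rank, d in shortlist:
            flags = (
                dz.flag_antigen_contacts(
                    d.mutations, ctx.structure, antigen,
                    cutoff=ctx.config.antigen_contact_cutoff,
                )
                if antigen
                else {}
            )
            final_rows.append(_design_row(n, rank, d, flags))
            mutant = ctx.solubility.mutate_chains(
                ctx.wt_chains,
                [ctx.seq_mutation(m) for m in d.mutations],
                ctx.identity_groups,
            )
            for cid, seq in mutant.items():
                fasta_lines.append(f">design_n{n}_rank{rank}|{'+'.join(d.names)}|chain_{cid}")
                fasta_lines.append(seq)
        log.append(f"final designs: {len(final_rows)}")
    else:
        log.append("no surviving mutations; empty design set")

    pd.DataFrame(final_rows).to_csv(outdir / "final_designs.csv", index=False)
    (outdir / "designs.fasta").write_text(
        "\n".join(fasta_lines) + ("\n" if fasta_lines else "")
    )
    config.to_yaml(outdir / "config.yaml")
    (outdir / "log.txt").write_text("\n".join(log) + "\n")
    _write_report(outdir, ctx, sites, records, groups, final_rows)
    return outdir


def run_scan(config: RunConfig, outdir: str | Path) -> Path:
    """Run stages (i)-(iii) only: sites and the single mutational scan."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx, predictor = build_context(config)
    export_profiles_csv(outdir / "profiles.csv", ctx.structure, ctx.intrinsic,
                        ctx.corrected)
    custom = [parse_position(p) for p in config.custom_sites]
    sites = dz.select_sites(ctx, custom)
    _sites_frame(ctx, sites).to_csv(outdir / "sites.csv", index=False)
    attempts, records = dz.single_scan(ctx, sites, predictor)
    _attempts_frame(attempts).to_csv(outdir / "scan_attempts.csv", index=False)
    _records_frame(records).to_csv(outdir / "scan_shortlist.csv", index=False)
    config.to_yaml(outdir / "config.yaml")
    return outdir


def _write_report(outdir: Path, ctx, sites, records, groups, final_rows) -> None:
    lines = ["# Design report", ""]
    lines.append("## Inputs")
    lines.append(f"- chains: {', '.join(ctx.structure.chain_ids)}")
    lines.append(
        "- identity groups: "
        + ", ".join("{" + ",".join(g) + "}" for g in ctx.identity_groups)
    )
    lines.append("")
    lines.append("## Phylogenetic profiles")
    for cid, pssm in sorted(ctx.pssms.items()):
        lines.append(
            f"- chain {cid}: {pssm.n_sequences} sequences, kind={pssm.kind}, "
            f"mean conservation {pssm.conservation.mean():.3f}"
        )
    lines.append("")
    wt_global = ctx.solubility.global_score(list(ctx.wt_chains.values()))
    lines.append("## Solubility")
    lines.append(f"- wild-type global solubility score: {wt_global:.4f}")
    lines.append("")
    lines.append(f"## Candidate sites ({len(sites)})")
    by_cat: dict[str, int] = {}
    for s in sites:
        for c in s.categories:
            by_cat[c] = by_cat.get(c, 0) + 1
    for c in dz.CATEGORY_ORDER:
        if c in by_cat:
            lines.append(f"- {c}: {by_cat[c]}")
    lines.append("")
    lines.append(f"## Single mutational scan ({len(records)} survivors)")
    for r in sorted(records, key=lambda r: -r.mutation_score)[:10]:
        lines.append(
            f"- {r.name}: dSol={r.delta_solubility:+.3f} "
            f"ddG={r.ddg.propagated:+.3f} score={r.mutation_score:.3f}"
        )
    lines.append("")
    lines.append("## Designs")
    for n in sorted(groups):
        top = groups[n][0]
        lines.append(
            f"- n={n}: {len(groups[n])} combinations, top score "
            f"{top.mutation_score:.3f} ({'+'.join(top.names)})"
        )
    lines.append("")
    lines.append(f"## Final shortlist ({len(final_rows)} designs)")
    for row in final_rows:
        lines.append(
            f"- n={row['n_mutations']} rank {row['rank']}: {row['mutations']} "
            f"(score {row['mutation_score']})"
        )
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
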