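"""Design pipeline: naming, site selection, scan, combination, checks."""

import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solstab.data import AMINO_ACIDS, UNIFORM_BACKGROUND
from solstab.designer import (
    CandidateSite,
    Design,
    DesignConfig,
    Mutation,
    MutationRecord,
    combine,
    final_shortlist,
    flag_antigen_contacts,
    format_mutation,
    interaction_check,
    knee_groups,
    mutation_score,
    normalize_delta_loglik,
    parse_mutation,
    select_best_groups,
    select_sites,
    single_scan,
)
from solstab.fixtures import make_helix_structure, make_msa
from solstab.phylo import Pssm
from solstab.pipeline import make_context
from solstab.stability import DdgEstimate, SurrogateDdgPredictor


def helix_ctx(seq, column_model=None, n_seqs=80, seed=0, **cfg_kwargs):
    structure = make_helix_structure({"A": seq})
    msa = make_msa(seq, n_seqs, 0.9, seed=seed, column_distributions=column_model)
    return make_context(structure, msa, DesignConfig(**cfg_kwargs))


def surrogate(ctx, pair_terms=None):
    return SurrogateDdgPredictor(ctx.exposure, ctx.contacts, pair_terms=pair_terms)


# sequence with three spatially clustered Arg sites (6, 10, 14); their
# alignment columns are enriched in both Lys (top) and Glu (runner-up),
# and both substitutions gain solubility and stability at every site
TRI_SEQ = "AKEAYRAEKRGELRKAEW"
TRI_COLS = {j: {"K": 0.50, "E": 0.25, TRI_SEQ[j]: 0.05} for j in (5, 9, 13)}


@pytest.fixture(scope="module")
def tri_ctx():
    return helix_ctx(TRI_SEQ, TRI_COLS)


@pytest.fixture(scope="module")
def tri_scan(tri_ctx):
    sites = select_sites(tri_ctx)
    return single_scan(tri_ctx, sites, surrogate(tri_ctx))


class TestMutationCodec:
    def test_canonical_name_format(self):
        assert format_mutation("L", "A", 24, None, "D") == "LA24D"

    def test_parse(self):
        m = parse_mutation("LA24D")
        assert (m.wt, m.chain, m.number, m.icode, m.mut) == ("L", "A", 24, None, "D")

    def test_insertion_code_round_trip(self):
        assert parse_mutation("LH100AD").icode == "A"
        assert format_mutation("L", "H", 100, "A", "D") == "LH100AD"

    @pytest.mark.parametrize("bad", ["", "LA24", "la24d", "L-24D", "LA24D7"])
    def test_unparsable_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_mutation(bad)

    @given(
        wt=st.sampled_from(AMINO_ACIDS),
        chain=st.sampled_from("ABH1"),
        number=st.integers(min_value=1, max_value=9999),
        icode=st.sampled_from([None, "A", "B"]),
        mut=st.sampled_from(AMINO_ACIDS),
    )
    @settings(deadline=None, max_examples=100)
    def test_round_trip_property(self, wt, chain, number, icode, mut):
        m = Mutation(wt, chain, number, icode, mut)
        assert parse_mutation(m.name) == m


class TestSelectSites:
    def test_demo_categories(self, demo):
        sites = {s.number: s for s in select_sites(demo)}
        assert "conservation" in sites[33].categories
        for resnum in (19, 20, 21):
            assert "sequence_solubility" in sites[resnum].categories
        for resnum in (10, 17, 24, 31):
            assert sites[resnum].categories == {"exposed_solubility"}

    def test_exposure_boundary_is_inclusive(self, demo):
        # a site at exactly 10% exposure counts as exposed, just below not
        site33 = next(s for s in select_sites(demo) if s.number == 33)
        cfg = demo.config
        assert cfg.exposure_threshold == 0.10
        at = dataclasses.replace(
            demo, exposure={**demo.exposure, site33.key: 0.10}
        )
        below = dataclasses.replace(
            demo, exposure={**demo.exposure, site33.key: 0.0999}
        )
        # conservation sites ignore exposure, so probe via the scan waiver:
        # at a "buried" conservation site a solubility loss is tolerated
        _, kept_at = single_scan(at, select_sites(at), surrogate(at))
        _, kept_below = single_scan(below, select_sites(below), surrogate(below))
        assert "TA33A" not in {r.name for r in kept_at}
        assert "TA33A" in {r.name for r in kept_below}

    def test_consensus_guard_blocks_exposed_solubility(self):
        conserved = {5: {"R": 0.75, "K": 0.20}}
        less_conserved = {5: {"R": 0.55, "K": 0.20}}
        guarded = helix_ctx("AKEAYRAEKGELKAE", conserved, pssm_mode="ll_pos")
        open_ = helix_ctx("AKEAYRAEKGELKAE", less_conserved, pssm_mode="ll_pos")
        assert guarded.pssms["A"].conservation[5] > 0.7
        assert guarded.pssms["A"].consensus(5) == "R"
        assert 6 not in {s.number for s in select_sites(guarded)}
        assert 6 in {s.number for s in select_sites(open_)}

    def test_site_cap_discards_exposed_solubility_class(self, demo):
        # core classes already exceed the cap: class-4-only sites vanish
        capped = dataclasses.replace(
            demo, config=dataclasses.replace(demo.config, max_sites=3)
        )
        sites = select_sites(capped)
        assert all(s.categories != {"exposed_solubility"} for s in sites)
        # ... and the core classes themselves are never truncated
        assert {s.number for s in sites} == {19, 20, 21, 33}

    def test_site_cap_fills_with_best_solubility_gains(self, demo):
        capped = dataclasses.replace(
            demo, config=dataclasses.replace(demo.config, max_sites=5)
        )
        sites = select_sites(capped)
        assert len(sites) == 5
        extras = [s for s in sites if s.categories == {"exposed_solubility"}]
        assert len(extras) == 1
        # the one admitted class-4 site carries the largest achievable gain
        gains = {}
        for s in select_sites(demo):
            if s.categories == {"exposed_solubility"}:
                best = max(
                    demo.delta_solubility(
                        [Mutation(s.wt, s.chain, s.number, s.icode, "K")]
                    )
                    for _ in [0]
                )
                gains[s.number] = best
        assert extras[0].number == max(gains, key=gains.get)

    def test_custom_sites_appended(self, demo):
        sites = select_sites(demo, custom_sites=[("A", 5, None)])
        custom = next(s for s in sites if s.number == 5)
        assert custom.categories == {"custom"}
        with pytest.raises(KeyError):
            select_sites(demo, custom_sites=[("A", 999, None)])

    def test_excluded_positions_and_chains(self, demo, demo_dimer):
        cfg = dataclasses.replace(
            demo.config, excluded_positions=frozenset({("A", 17, None)})
        )
        sites = select_sites(dataclasses.replace(demo, config=cfg))
        assert 17 not in {s.number for s in sites}

    def test_excluded_chain_moves_design_to_other_group_member(self):
        from solstab.fixtures import make_design_fixture

        structure, msa = make_design_fixture(n_chains=2)
        ctx = make_context(
            structure, msa, DesignConfig(excluded_chains=frozenset("A"))
        )
        assert {s.chain for s in select_sites(ctx)} == {"B"}


class TestSingleScan:
    def test_excluded_targets_never_survive(self):
        ctx = helix_ctx("AKEAYSAEKGELKAE", {5: {"C": 0.5, "M": 0.3, "S": 0.1}})
        sites = select_sites(ctx, custom_sites=[("A", 6, None)])
        attempts, records = single_scan(ctx, sites, surrogate(ctx))
        dropped = {a.mutation.name: a.drop_reason for a in attempts}
        assert dropped.get("SA6C") == "excluded_target"
        assert dropped.get("SA6M") == "excluded_target"
        assert not any(r.mutation.mut in "CM" for r in records)

    def test_demo_drop_reasons(self, demo):
        attempts, records = single_scan(demo, select_sites(demo), surrogate(demo))
        status = {a.mutation.name: a.drop_reason for a in attempts}
        assert status["HA13K"] == "ddg"  # solubilising but destabilising
        assert status["LA19E"] == "ddg"
        assert status["TA33A"] == "delta_solubility"  # exposed conservation site
        assert status["RA17K"] is None
        assert {r.name for r in records} == {
            n for n, reason in status.items() if reason is None
        }

    def test_buried_conservation_site_tolerates_solubility_loss(self, demo):
        buried = dataclasses.replace(
            demo, exposure={**demo.exposure, ("A", 33, None): 0.05}
        )
        _, records = single_scan(buried, select_sites(buried), surrogate(buried))
        rec = next(r for r in records if r.name == "TA33A")
        assert rec.delta_solubility < 0
        assert rec.ddg.propagated < 0

    def test_site_without_allowed_substitutions_is_not_an_error(self, demo):
        # position 1 is highly conserved as the wild type: empty shortlist
        attempts, records = single_scan(
            demo, select_sites(demo, custom_sites=[("A", 1, None)]), surrogate(demo)
        )
        assert not any(r.mutation.number == 1 for r in records)

    def test_homodimer_propagates_ddg_twofold(self, demo, demo_dimer):
        _, mono = single_scan(demo, select_sites(demo), surrogate(demo))
        _, dimer = single_scan(
            demo_dimer, select_sites(demo_dimer), surrogate(demo_dimer)
        )
        mono_by_name = {r.name: r for r in mono}
        assert dimer and {r.name for r in dimer} == set(mono_by_name)
        for r in dimer:
            assert r.ddg.propagated == pytest.approx(2 * r.ddg.mean)
            assert r.ddg.mean == pytest.approx(mono_by_name[r.name].ddg.mean)


def _dummy_site(chain="A", number=1):
    return CandidateSite(chain, number, None, "R", 0.5, number - 1, {"custom"})


def _record(chain, number, dll, score=1.0, ddg=-0.5, dsol=0.1, mut="K"):
    return MutationRecord(
        Mutation("R", chain, number, None, mut),
        _dummy_site(chain, number),
        dsol,
        DdgEstimate(ddg),
        dll,
        mutation_score=score,
    )


def _flat_pssm(value: float, L: int = 4) -> Pssm:
    rng = np.random.default_rng(0)
    matrix = np.full((L, 20), value)
    return Pssm("loglik", matrix, UNIFORM_BACKGROUND.copy(),
                np.full(L, 0.5), 100, "R" * L)


class TestNormalisation:
    def test_each_chain_uses_its_own_sd(self):
        rng = np.random.default_rng(1)
        pssm_a = _flat_pssm(0.0)
        pssm_a.matrix[:] = rng.normal(0, 2.0, pssm_a.matrix.shape)
        pssm_b = _flat_pssm(0.0)
        pssm_b.matrix[:] = rng.normal(0, 0.5, pssm_b.matrix.shape)
        records = [_record("A", 1, dll=1.0), _record("B", 2, dll=1.0)]
        normalize_delta_loglik(records, {"A": pssm_a, "B": pssm_b})
        assert records[0].delta_loglik_norm == pytest.approx(1.0 / pssm_a.sd)
        assert records[1].delta_loglik_norm == pytest.approx(1.0 / pssm_b.sd)
        assert records[0].delta_loglik_norm != records[1].delta_loglik_norm

    def test_degenerate_constant_matrix_normalises_to_zero(self):
        records = [_record("A", 1, dll=1.0)]
        normalize_delta_loglik(records, {"A": _flat_pssm(0.7)})
        assert records[0].delta_loglik_norm == 0.0


class TestMutationScore:
    def test_arithmetic(self):
        assert mutation_score(0.0, 0.0, 0.0) == 0.0
        assert mutation_score(0.5, -1.0, 0.2) == pytest.approx(1.7)

    def test_monotonicity(self):
        base = mutation_score(0.5, -1.0, 0.2)
        assert mutation_score(0.6, -1.0, 0.2) > base
        assert mutation_score(0.5, -0.9, 0.2) < base
        assert mutation_score(0.5, -1.0, 0.3) > base


class TestCombine:
    def test_pair_scores_are_additive(self, tri_ctx, tri_scan):
        _, records = tri_scan
        groups = combine(tri_ctx, records, max_mutations=3)
        by_name = {r.name: r for r in records}
        for d in groups[2]:
            assert d.ddg_sum == pytest.approx(
                sum(by_name[n].ddg.propagated for n in d.names)
            )
            assert d.delta_loglik_norm_sum == pytest.approx(
                sum(by_name[n].delta_loglik_norm for n in d.names)
            )

    def test_interaction_flag_matches_contact_map(self, tri_ctx, tri_scan):
        _, records = tri_scan
        groups = combine(tri_ctx, records, max_mutations=3)
        for designs in groups.values():
            for d in designs:
                expected = any(
                    tri_ctx.contacts.in_contact(a.site, b.site)
                    for a, b in itertools.combinations(d.mutations, 2)
                )
                assert d.potentially_interacting == expected

    def test_runner_up_substitution_in_pairs_but_not_triples(self, tri_ctx, tri_scan):
        _, records = tri_scan
        muts_per_site = {}
        for r in records:
            muts_per_site.setdefault(r.mutation.site, []).append(r)
        assert any(len(v) >= 2 for v in muts_per_site.values())
        groups = combine(tri_ctx, records, max_mutations=3)
        pair_muts = {n for d in groups[2] for n in d.names}
        triple_muts = {n for d in groups[3] for n in d.names}
        runner_ups = set()
        for site, recs in muts_per_site.items():
            ranked = sorted(recs, key=lambda r: -r.mutation_score)
            runner_ups.update(r.name for r in ranked[1:])
        assert runner_ups & pair_muts
        assert not runner_ups & triple_muts

    def test_one_mutation_per_logical_site(self, tri_ctx, tri_scan):
        _, records = tri_scan
        groups = combine(tri_ctx, records, max_mutations=3)
        for designs in groups.values():
            for d in designs:
                sites = [m.site for m in d.mutations]
                assert len(sites) == len(set(sites))

    def test_negative_score_singles_are_discarded(self, tri_ctx, tri_scan):
        _, records = tri_scan
        bad = _record("A", 2, dll=0.0, score=-0.5, mut="Q")
        groups = combine(tri_ctx, list(records) + [bad], max_mutations=2)
        assert bad.name not in {n for d in groups[1] for n in d.names}
        assert bad.name not in {n for d in groups[2] for n in d.names}

    def test_solubility_recomputed_on_full_mutant(self, tri_ctx, tri_scan):
        _, records = tri_scan
        groups = combine(tri_ctx, records, max_mutations=2)
        for d in groups[2]:
            assert d.delta_solubility == pytest.approx(
                tri_ctx.delta_solubility(d.mutations)
            )


def _design_with_score(score, n=1):
    muts = tuple(Mutation("R", "A", 10 + i, None, "K") for i in range(n))
    return Design(muts, 0.1, -0.5, 0.2, score)


class TestBestGroupsAndShortlist:
    def test_knee_rule_declared_example(self):
        groups = {
            n: [_design_with_score(s, n)]
            for n, s in zip(range(1, 5), [1.0, 2.0, 3.0, 3.1])
        }
        assert select_best_groups(groups) == {3}

    def test_linear_growth_selects_largest_group(self):
        assert knee_groups({1: 1.0, 2: 2.0, 3: 3.0, 4: 4.0}) == {4}

    def test_single_group(self):
        assert knee_groups({1: 0.7}) == {1}

    def test_accelerating_tail_added_to_best_set(self):
        # early knee at n=2, but the last gain exceeds the earlier mean
        assert 4 in knee_groups({1: 1.0, 2: 2.0, 3: 2.1, 4: 4.0})

    def test_shortlist_three_per_best_one_per_other(self):
        groups = {
            n: [_design_with_score(1.0 + n - 0.1 * r, n) for r in range(4)]
            for n in range(1, 6)
        }
        picks = final_shortlist(groups, {3})
        assert len(picks) == 3 + 4
        assert [n for n, _, _ in picks] == sorted(n for n, _, _ in picks)

    def test_shortlist_with_small_best_group(self):
        groups = {1: [_design_with_score(1.0)], 2: [_design_with_score(2.0, 2)] * 2}
        picks = final_shortlist(groups, {2})
        assert sum(1 for n, _, _ in picks if n == 2) == 2

    def test_shortlist_two_best_groups(self):
        groups = {
            n: [_design_with_score(1.0 + n, n) for _ in range(3)]
            for n in range(1, 5)
        }
        assert len(final_shortlist(groups, {2, 3})) == 3 + 3 + 1 + 1


def _flagged_pair(tri_ctx, records, site_a=6, site_b=10, mut="K"):
    by = {(r.mutation.number, r.mutation.mut): r for r in records}
    groups = combine(tri_ctx, [by[(site_a, mut)], by[(site_b, mut)]], max_mutations=2)
    design = groups[2][0]
    assert design.potentially_interacting
    return design


class TestInteractionCheck:
    def test_unflagged_design_returned_unchanged(self, tri_ctx, tri_scan):
        _, records = tri_scan
        d = Design(
            tuple(r.mutation for r in records[:2]), 0.1, -0.4, 0.2, 1.0,
            potentially_interacting=False,
        )
        assert interaction_check(tri_ctx, d, surrogate(tri_ctx), records) is d

    def test_fewer_than_two_mutations_rejected(self, tri_ctx, tri_scan):
        _, records = tri_scan
        d = Design((records[0].mutation,), 0.1, -0.4, 0.2, 1.0, True)
        with pytest.raises(ValueError):
            interaction_check(tri_ctx, d, surrogate(tri_ctx), records)

    def test_additive_predictor_preserves_ddg_sum(self, tri_ctx, tri_scan):
        _, records = tri_scan
        design = _flagged_pair(tri_ctx, records)
        checked = interaction_check(tri_ctx, design, surrogate(tri_ctx), records)
        assert checked.checked
        assert set(checked.names) == set(design.names)
        assert checked.ddg_sum == pytest.approx(design.ddg_sum)

    def test_disruptive_mutation_replaced_by_alternative(self, tri_ctx, tri_scan):
        _, records = tri_scan
        design = _flagged_pair(tri_ctx, records)
        pair = frozenset(m.site for m in design.mutations)
        by_name = {r.name: r for r in records}
        # a pair term large enough to void the second Lys, small enough
        # that the Glu alternative at the same site stays stabilising
        k_ddg = min(abs(by_name[n].ddg.propagated) for n in design.names)
        e_ddg = min(
            abs(r.ddg.propagated) for r in records if r.mutation.mut == "E"
        )
        assert e_ddg > k_ddg
        term = (k_ddg + e_ddg) / 2
        pred = surrogate(tri_ctx, pair_terms={pair: term})
        checked = interaction_check(tri_ctx, design, pred, records)
        assert checked.n_mutations == 2
        muts = {m.mut for m in checked.mutations}
        assert muts == {"K", "E"}
        assert checked.ddg_sum < 0

    def test_site_removed_when_no_alternative_works(self, tri_ctx, tri_scan):
        _, records = tri_scan
        design = _flagged_pair(tri_ctx, records)
        pair = frozenset(m.site for m in design.mutations)
        pred = surrogate(tri_ctx, pair_terms={pair: 50.0})
        checked = interaction_check(tri_ctx, design, pred, records)
        assert checked.n_mutations == 1
        assert checked.checked


class TestAntigenContacts:
    def _complex(self, gap):
        return make_helix_structure(
            {"A": "MKTAYIAKQRLE", "G": "GSTNQW"}, offsets={"G": (gap, 0.0, 0.0)}
        )

    def test_flags_match_brute_force(self):
        s = self._complex(8.0)
        muts = [Mutation(res.aa, "A", res.number, None, "K")
                for res in s.chain("A").residues]
        flags = flag_antigen_contacts(muts, s, ["G"], cutoff=4.5)
        antigen_xyz = np.array(
            [a.coord for r in s.chain("G").residues for a in r.atoms]
        )
        for m in muts:
            res = s.residue(m.site)
            d = np.sqrt(
                ((np.array([a.coord for a in res.atoms])[:, None, :]
                  - antigen_xyz[None, :, :]) ** 2).sum(-1)
            ).min()
            assert flags[m.name] == (d <= 4.5)
        assert any(flags.values())

    def test_distant_antigen_never_flagged(self):
        s = self._complex(40.0)
        muts = [Mutation("M", "A", 1, None, "K")]
        assert flag_antigen_contacts(muts, s, ["G"]) == {"MA1K": False}

    def test_unknown_antigen_chain(self):
        s = self._complex(8.0)
        with pytest.raises(ValueError, match="Z"):
            flag_antigen_contacts([], s, ["Z"])


class TestLabelInvariance:
    def test_chain_renaming_permutes_names_not_scores(self):
        from solstab.fixtures import DEMO_COLUMN_MODEL, DEMO_SEQUENCE

        def scan_for(chain_id):
            structure = make_helix_structure({chain_id: DEMO_SEQUENCE})
            msa = make_msa(DEMO_SEQUENCE, 80, 0.85, seed=0,
                           column_distributions=DEMO_COLUMN_MODEL)
            ctx = make_context(structure, msa, DesignConfig())
            _, records = single_scan(ctx, select_sites(ctx), surrogate(ctx))
            return records

        a = {r.name: r for r in scan_for("A")}
        x = {r.name.replace("X", "A", 1): r for r in scan_for("X")}
        assert set(a) == set(x)
        for name, rec in a.items():
            assert x[name].mutation_score == pytest.approx(rec.mutation_score)
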