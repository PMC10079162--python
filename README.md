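# solstab

Automated co-optimisation of protein **solubility** and **conformational
stability** by phylogenetically filtered mutational design.

Biologics — antibodies, nanobodies, enzymes — are often discovered with
good function but poor developability: they aggregate, express badly, or
unfold under manufacturing and formulation stress. Solubility and
conformational stability are the two biophysical traits that underpin
developability, and they are frequently conflicting: mutations that fix
one tend to break the other. `solstab` implements a fully automated
design pipeline that proposes combinations of substitutions predicted to
improve both traits at once, and that uses phylogenetic information to
avoid the most expensive class of prediction error — mutations predicted
to be stabilising that are destabilising in reality.

## The method

Inputs are a structure in PDB format and a multiple sequence alignment
of homologs per chain. The pipeline then runs five stages:

1. **Input processing.** Chain sequences are taken from SEQRES (falling
   back to the coordinate records), identical chains are grouped (they
   are encoded by one gene, so mutations are always mirrored across the
   group), and a position specific scoring matrix (PSSM) of natural-log
   likelihood ratios `ln(f_a / q_a)` is built per chain from the MSA
   (gap-excluded counts, background-proportional pseudocount). Below 50
   sequences a raw-frequency PWM is used instead. Per-column
   conservation is `CI = 1 − H/ln 20`, the normalised-entropy
   complement. Relative solvent exposure (Shrake–Rupley sphere
   sampling, normalised by Gly-X-Gly reference areas) and a heavy-atom
   contact map are computed from the coordinates.
2. **Candidate sites** come from four classes: poorly soluble *exposed*
   residues of the intrinsic (sequence-based) solubility profile;
   members of surface aggregation hotspots in the structurally
   corrected profile; conserved positions (`CI > 0.25`) where the wild
   type is rare (`log-likelihood ≤ 0`, or PWM frequency `< 0.05`); and
   exposed positions with solubilising, PSSM-permitted substitutions —
   unless `CI > 0.7` and the wild type is already the consensus.
   Custom sites may be added, chains/positions excluded.
3. **Single mutational scan.** At each site every PSSM-permitted
   substitution (default: `log-likelihood > 0` *and*
   `Δlog-likelihood > 0`) is scored. Oxidation-prone targets (Cys, Met
   by default) are never introduced. Mutations that lose solubility are
   dropped (except at buried conservation sites), ΔΔG is predicted
   (negative = stabilising), multiplied by the identity-group size, and
   non-stabilising mutations are dropped. Survivors are ranked by the
   **Mutation Score**

   `MS = w_s·ΔSol − w_g·ΔΔG + w_p·Δll/σ(PSSM)`,

   with unit weights by default.
4. **Combination.** Singles are combined recursively: ΔΔG and
   normalised Δlog-likelihood add, the solubility change is recomputed
   on the fully mutated sequences. From triples onward only the
   top-ranked substitution per site is used. Designs whose sites touch
   in the contact map are flagged *potentially interacting*. Among the
   groups (all designs with the same mutation count) a knee rule on the
   growth of the top Mutation Score picks the best trade-off sizes; the
   shortlist takes the three best designs per best group and one per
   other group.
5. **Interaction check.** Flagged shortlisted designs are re-evaluated
   sequentially with a context-aware predictor; a mutation that turns
   destabilising in context is replaced by one of up to three ranked
   alternatives at its position, or its site is removed.

ΔΔG prediction is pluggable: a transparent deterministic surrogate is
bundled, and externally computed values (e.g. from a physics-based
energy function) can be injected from CSV. The solubility model is a
profile-based surrogate (z-scored hydropathy, net charge, β-sheet
propensity, 7-residue window, global score with a penalty for residues
below −1); an external predictor's scores can likewise be imported.

### The FDR benchmark

The companion `benchmark` module quantifies why the phylogenetic filter
is in the pipeline. Given records pairing experimental and predicted
ΔΔG, it counts the sign quadrants (FP = predicted stabilising,
experimentally destabilising) and computes `FDR = FP/(FP+TP)` without
filtering, for mutations with positive log-likelihood, and for
mutations that also increase frequency over the wild type. Significance
is assessed by explicit random resampling: the p-value is the
probability that a size-matched random subset reaches an FDR at least
as low, which separates the effect of the filter from that of shrinking
the dataset.

## Worked example

The package ships deterministic synthetic fixtures (ideal α-helix PDBs,
column-controlled MSAs, stratified benchmark tables), so the whole
pipeline runs without downloads:

```bash
solstab fixtures --out fixtures --seed 0
solstab design --structure fixtures/demo.pdb --msa fixtures/demo_msa.fasta \
    --max-mutations 5 --out run
cat run/log.txt
```

```
chains: A
identity groups: {A}
candidate sites: 11
scan attempts: 11; survivors: 4
groups: n=1:4 n=2:6 n=3:4 n=4:1
best groups: [2, 3]
final designs: 8
```

The demo helix carries an aggregation-prone V/L/I patch and several
arginines whose homolog columns are enriched in lysine. The scan keeps
the four Arg→Lys substitutions (solubilising *and* mildly stabilising
under the surrogate); the patch positions are proposed but rejected at
the stability filter, which `run/scan_attempts.csv` records with drop
reason `ddg`. The shortlist (`run/final_designs.csv`) contains, per the
group rule, three designs each for the best group sizes 2 and 3 and one
for sizes 1 and 4 — e.g. the top pair:

```
n_mutations,rank,mutations,delta_solubility,ddg_sum,...,mutation_score
2,1,RA17K+RA24K,0.004064,-0.253803,...,1.367271
```

meaning both solubility (ΔSol = +0.004) and stability
(ΔΔG = −0.25 kcal/mol) are predicted to improve. The FDR benchmark on
the synthetic 2000-record table:

```bash
solstab benchmark fixtures/demo_benchmark.csv --out fdr.csv --n-resample 10000
```

```
      filter  n_kept  TP  FP  TN  FN      FDR  pvalue
        none    2000 684 278 557 481 0.288981     NaN
      ll_pos    1512 547 181 426 358 0.248626  0.0001
ll_and_delta     984 412  73 278 221 0.150515  0.0001
```

The false discovery rate drops from ~29% to ~15% under the
Δlog-likelihood filter, and the resampling p-value shows the drop is
not explained by the smaller subset size.

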