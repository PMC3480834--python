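# mirseed

Microarray-based identification of microRNA targets from transcript-level
expression changes. When a miRNA is overexpressed in a cell line, its
direct targets are destabilized, so transcripts carrying the miRNA's seed
sites should be enriched among the down-regulated genes. `mirseed` turns
that idea into a reusable, fully testable pipeline:

1. **Seed-site scanning** — derive the four canonical site strings of a
   mature miRNA (6mer, 7mer-m8, 7mer-1A, 8mer) and scan 3'UTRs with
   mutually exclusive site-type assignment: each occurrence of the 6mer
   core is attributed to the strongest class whose context matches
   (8mer > 7mer-m8 > 7mer-1A > 6mer).
2. **Gene-set partitioning** — an optional variance filter on replicate
   arrays, then disjoint up / down / no-change sets from a logFC table
   (threshold |logFC| ≥ log2(fc_cutoff), default fc_cutoff 1.1; the
   no-change set is the genes nearest logFC 0, size-matched to the down
   set).
3. **Seed-site enrichment** — fraction of genes per set with a site,
   compared by a two-sided Fisher exact test; plus two descriptive
   counting modes (size-corrected occurrence subsampling, occurrences per
   kb).
4. **Unbiased word analysis** — for every k-mer w, per-gene occurrence
   rates r_i = x_i / L_i along the list ranked by ascending logFC give a
   mean-centered running sum R_j = Σ_{i≤j}(r_i − r̄) with max-deviation
   statistic D = max_j R_j; D is standardized against random permutations
   of the gene order into a Z-score and empirical p, and all 4^k words are
   ranked by Z. A true target word peaks at the head of the list (the
   down-regulated end).
5. **Target report & anti-correlation** — candidate targets are down-set
   genes with ≥ 1 strong (7mer-m8 / 7mer-1A / 8mer) site; a Pearson
   correlation operation (exact t-transform p) tests miRNA–mRNA
   anti-correlation across tumor samples.

A synthetic-data module generates complete studies with known ground truth
(planted seed-site carriers, carrier logFC down-shift, replicate-array
noise, correlated sample pairs), so every stage is testable without any
download. The motivating use case is miR-143 in colon cancer — its 7mer-m8
site is `TCATCTC`, and hexokinase 2 (HK2) carries the 8mer `TCATCTCA` in
its 3'UTR — but every operation takes an arbitrary mature miRNA sequence
and arbitrary UTR/expression inputs.

## Worked example

```python
from mirseed import AnalysisConfig, MatureMiRNA, define_gene_sets, derive_seed_sites
from mirseed.seed_model import scan_utrs
from mirseed.site_enrichment import COMBINED_LABEL, gene_fraction_enrichment
from mirseed.synthetic_data import simulate_scenario
from mirseed.word_enrichment import rank_sequences, rank_words

mir143 = MatureMiRNA("hsa-miR-143-3p", "UGAGAUGAAGCACUGUAGCUC")
sites = derive_seed_sites(mir143)
print("7mer-m8:", sites.site_7mer_m8, " 8mer:", sites.site_8mer)

# synthetic study: 1000 genes, 30% carry a planted 7mer site, carriers
# shifted down by 0.4 logFC units on top of N(0, 0.3^2) noise
study = simulate_scenario(rng_seed=7, planted_word=sites.site_7mer_m8, delta=0.4)
sets = define_gene_sets(study.fc, AnalysisConfig())
counts = scan_utrs(study.utrs, sites)
for r in gene_fraction_enrichment(sets, counts, COMBINED_LABEL):
    frac_a = r.a_with / (r.a_with + r.a_without)
    frac_b = r.b_with / (r.b_with + r.b_without)
    print(f"{r.comparison}: {100*frac_a:.1f}% vs {100*frac_b:.1f}% carriers, p = {r.p_value:.2e}")

words = rank_words(rank_sequences(study.utrs, study.fc), k=7, rng_seed=7)
print(words[["word", "z_score", "empirical_p", "rank"]].head(3).to_string(index=False))
```

Output:

```
7mer-m8: TCATCTC  8mer: TCATCTCA
down-vs-up: 54.5% vs 9.0% carriers, p = 2.14e-33
down-vs-nochange: 54.5% vs 25.6% carriers, p = 3.97e-16
   word   z_score  empirical_p  rank
TCATCTC 14.803984     0.009901     1
CATCTCC  9.208860     0.009901     2
CATCTCT  7.058097     0.009901     3
```

Reading: 54.5% of down-regulated genes carry a strong miR-143 site versus
9.0% of up-regulated genes — the Fisher test rejects equality decisively —
and the unbiased word analysis recovers the planted 7mer as the
top-ranked word of all 16384, with a permutation Z of 14.8 (empirical
p = 1/101, the floor at 100 permutations).

## Command line

Every stage is also a `mirseed` subcommand communicating through TSV files:

```bash
mirseed simulate --seed 17 --outdir fixtures/
mirseed scan --mirna-seq UGAGAUGAAGCACUGUAGCUC --utrs fixtures/utrs.fa --out sites.tsv
mirseed sets --fc fixtures/fc.tsv --expr fixtures/expr.tsv --out sets.tsv
mirseed enrich --sets sets.tsv --sites sites.tsv --method gene-fraction --out enrich.tsv
mirseed words --fc fixtures/fc.tsv --utrs fixtures/utrs.fa -k 7 --out words.tsv \
    --profile-word TCATCTC --profile-out profile.tsv
mirseed targets --sets sets.tsv --sites sites.tsv --fc fixtures/fc.tsv --out targets.tsv
mirseed run-all --config run.json --outdir results/
```

`run-all` chains all stages and writes a `manifest.json` (config echo,
input checksums, seeds, per-stage row counts) sufficient to re-run
bit-identically.

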