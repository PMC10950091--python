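# speciescall

Species identification from amplicon SNP genotype panels.

Large-scale genetic monitoring of Pacific salmon (genetic stock
identification, parentage-based tagging) genotypes tens of thousands of
samples per year on species-specific GT-seq panels. Misidentified,
non-target species slip into these collections, show poor genotyping
success, and waste laboratory effort unless they are diagnosed and re-routed
automatically. A small set of species-informative SNPs embedded in the
existing panels solves this: `speciescall` implements the weighted
allelic-association scoring system that turns those genotypes into a species
call, plus the simulation machinery used to validate such marker sets.

## The scoring system

A *species-seq* file maps each bi-allelic locus ``l`` to the species
expected homozygous for allele 1, those expected homozygous for allele 2,
and a weight ``w_l`` (2 for single-species diagnostic variants, 1 for
variants informative for a subset; tri-allelic positions get two bi-allelic
entries). For a sample, every species ``s`` accumulates

    S_s = Σ_l  w_l · d_l(s),   d_l(s) = +1  hom. genotype matches s's allele,
                                        −1  hom. genotype matches the other allele,
                                         0  heterozygous / missing / foreign

Only homozygotes score: the panel targets fixed differences, so heterozygous
calls signal contamination, hybrids, or shared polymorphisms and are merely
counted. Two normalisers turn scores into a call:

* ``M_s`` — absolute maximum score (complete, expected data). A call is
  made only if some species reaches ``S_s/M_s ≥ thresMS`` (default 0.5).
* ``P_s`` — maximum possible score given this sample's scorable loci.
  Candidates are the species within ``buffMP`` (default 1e-3) of the best
  ``S_s/P_s``; multi-candidate lists are pruned of species with
  ``S_s/M_s < pruneMS`` (default 0.34).

Samples whose heterozygosity over genotyped informative loci exceeds
``thresHET`` (default 0.06) are flagged ``-ReviewHET``.

Two validation studies quantify robustness: random genotype *omission*
(missing data never removes the true species from a call — its
possible-score proportion stays at 1) and low-frequency *shared
polymorphisms* (Hardy–Weinberg draws of an alternative allele at frequency
``p``, which only harm calls through the ``p²`` homozygote mass).

The package ships a synthetic 13-taxon salmonid reference panel
(`speciescall.refpanel_synthetic`): 51 variant positions in 19 amplicons
with the deployed marker set's exact bookkeeping, but *synthesised*
allele-to-species bipartitions — see `docs/methods.md` for what that does
and does not validate.

## Worked example

```python
>>> import speciescall as sc
>>> panel = sc.tp1_panel()          # 3 species (X, Y, Z), 4 loci
>>> card = sc.score_sample({"L1": "AA", "L2": "CC", "L3": "TT", "L4": "CC"}, panel)
>>> card.scores
{'X': 7.0, 'Y': -1.0, 'Z': -3.0}
>>> sc.call_from_scorecard(card).render()
'X'
>>> sc.call_sample({"L1": "AG", "L2": "CC", "L3": "TT", "L4": "CC"}, panel).render()
'X-ReviewHET'
>>> sc.call_sample({"L2": "CC"}, panel).render()
'NoCall'
```

The complete X profile reaches its absolute maximum (7 of 7 → called `X`);
one heterozygous locus drops the score to 5/7 but leaves the ranking intact
while tripping the 6% heterozygosity review flag; a single genotyped locus
(best score 1/7 < 0.5) fails the call gate.

The same logic drives the CLI:

```sh
callspecies fixtures --out-dir fx
callspecies call --genotypes fx/toy_genotypes.csv --speciesseq fx/toy_speciesseq.csv -o called.csv
callspecies simulate missing --speciesseq fx/toy_speciesseq.csv --reps 1000 --seed 1 -o sim.csv
callspecies genotype --fastq fx/toy_X.fastq --probes fx/toy_probes.csv -o geno.csv
```

`called.csv` is the input table plus two columns, e.g. `SpeciesCall=X` and
`HetGenotyped=HET=0;GT=4` (heterozygous and successfully genotyped
species-informative loci).

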