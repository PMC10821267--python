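# hlaseq

HLA genotyping and allele-specific expression estimation from bulk RNA-seq,
with matched tumor/adjacent-normal cohort statistics.

The HLA complex (chromosome 6p21.3) is the most polymorphic region of the
human genome. Standard RNA-seq pipelines align reads against a reference
genome that carries one generic sequence per HLA gene, so both the genotype
and the expression of an individual's actual alleles are mis-estimated.
`hlaseq` addresses this for researchers studying tumor immunology and immune
escape: it types classical (HLA-A/-B/-C, -DP/-DQ/-DR) and non-classical
(-E/-F/-G, -DO/-DM) Class I and II loci directly from RNA-seq reads, then
quantifies *personalized* (allele-specific) expression against a
transcriptome in which the generic HLA transcripts are replaced by the
sample's own typed alleles, and finally compares tumor against matched
normal tissue.

## Method

**Reference library.** Alleles are stored exon-by-exon under the standard
nomenclature `LOCUS*f1:f2:f3:f4` (antigen group : protein : synonymous :
non-coding, with optional expression suffix). Public databases leave many
alleles incomplete — often only the peptide-binding exons (2–3 for Class I,
2 for Class II) are sequenced — so missing exons are reconstructed by copying
them from the closest same-locus allele (highest sequence identity over the
exons both alleles carry), breaking ties in favor of confirmed, common,
well-documented alleles.

**Genotyping.** Candidate reads are taken from an alignment by three rules:
proper pairs on chromosome 6, pairs with exactly one mate mapped and that
mate on chromosome 6, and fully unmapped pairs. A read pair is *compatible*
with an allele when both mates align ungapped to the allele's
concatenated-exon transcript within a small mismatch budget. With binary
selection variables $y_a$ and read-coverage variables $x_r$, the genotype of
all loci is solved jointly in a single integer linear program:

$$\max \sum_r w_r x_r - \lambda \sum_a y_a
\quad\text{s.t.}\quad 1 \le \sum_{a \in \ell} y_a \le 2 \;\;\forall \ell,
\qquad x_r \le \sum_{a \sim r} y_a,$$

maximizing the number of read pairs explained by the selection, one or two
alleles per locus. The per-allele penalty $\lambda$ decides zygosity by
parsimony: a locus is called homozygous unless a second allele explains at
least $\lambda$ additional reads. An exhaustive brute-force solver provides
an independent oracle for the ILP. Accuracy against a truth genotype is
scored at G-group resolution (alleles identical over the peptide-binding
exons are interchangeable; a group is named by its lowest-numbered member's
first three fields plus `G`).

**Expression.** Transcript abundance is estimated by the standard generative
EM over read–transcript compatibility and reported as TPM with
effective-length normalization; gene TPM is the sum of the gene's transcript
TPMs. Homozygous genotypes contribute one sequence (copy number 2) to keep
the mixture identifiable.

**Cohorts.** Tumor and adjacent-normal samples are matched by identical
classical Class I genotype at three fields of resolution. Per-gene
differences are tested with Student's t-test on log2(TPM+1), Bonferroni
corrected, with a fold-change filter for the strict significance call.
Immune-cell fraction tables from an external deconvolution tool are compared
with the same machinery.

A first-class synthetic-data module (`hlaseq.simulate`) generates toy allele
libraries with known G-group structure, exon-truncated libraries, paired-end
reads from known genotypes, and matched cohorts with planted effects, so the
whole workflow is testable end to end without downloads.

## Worked example

```python
import hlaseq as h

cfg = h.SimulationConfig(seed=7, loci=("HLA-A", "HLA-B"), alleles_per_locus=10)
lib, ggroups = h.generate_toy_library(cfg)

# simulate a heterozygous HLA-A and homozygous HLA-B individual
genotype = {"HLA-A*02:01:01": 1.0, "HLA-A*06:01:01": 1.0, "HLA-B*04:01:01": 2.0}
pairs, truth, true_tpm = h.simulate_reads(genotype, lib, cfg, seed=7)

cm = h.build_compatibility_matrix(pairs, lib)
call = h.solve_genotype_ilp(cm, lambda_hom=1.0)
for locus in sorted(call.calls):
    lc = call.calls[locus]
    print(f"{locus}: {lc.allele1} / {lc.allele2}"
          f"  (homozygous={lc.homozygous}, explains {lc.explained_reads:.0f} pairs)")

txome = h.build_personalized_transcriptome({}, [], call, lib, {})
print(h.quantify_em(pairs, txome).transcripts.round(1))
```

prints

```
HLA-A: HLA-A*02:01:01 / HLA-A*06:01:01  (homozygous=False, explains 518 pairs)
HLA-B: HLA-B*04:01:01 / HLA-B*04:01:01  (homozygous=True, explains 510 pairs)
                eff_length  est_count       tpm
HLA-A*02:01:01       944.0      252.2  245315.4
HLA-A*06:01:01       944.0      265.8  258575.6
HLA-B*04:01:01       944.0      510.0  496108.9
```

Both loci are typed back exactly from 1029 simulated pairs (the HLA-B call
is correctly homozygous: adding any second allele would explain fewer than
λ = 1 extra pairs), and the allele-specific TPMs reflect the simulated 1:1:2
molar abundances; TPM always sums to 10⁶.

The same workflow is available from the shell:

```bash
hlaseq simulate library --seed 1 --out lib/
hlaseq simulate reads --library lib/ --allele 'HLA-A*02:01:01' \
    --allele 'HLA-A*06:01:01' --out reads/
hlaseq type --reads1 reads/reads_1.fastq --reads2 reads/reads_2.fastq \
    --library lib/ --out genotype.tsv
hlaseq extract --alignment sample.bam --out1 r1.fastq --out2 r2.fastq
hlaseq quantify --reads1 r1.fastq --reads2 r2.fastq --reference txome.fasta \
    --txt2gene t2g.tsv --genotype genotype.tsv --library lib/ --out quant/
hlaseq match-pairs --tumor tumors.tsv --normal normals.tsv --out pairs.tsv
hlaseq diffexp --tumor tumor_tpm.tsv --normal normal_tpm.tsv --out diffexp.tsv
```

Every command writes a JSON manifest (parameters, seed, input checksums)
alongside its outputs.

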