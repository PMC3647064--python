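# paraprune

Detection and pruning of wrongly assigned paralogous sequences and
cross-contamination in phylogenomic supermatrices.

## The problem

Phylogenomic studies built from EST/transcriptome libraries depend on
orthology prediction to group sequences from different taxa into
single-gene partitions. Reciprocal-best-hit style predictors can be fooled
by **reciprocal lack**: when paralog *A* of a closely related gene pair is
present in the reference taxa but missing from a query library, while
paralog *B* shows the opposite pattern, the forward search finds *B*, the
back-check returns *A*, reciprocity appears satisfied, and *B* is silently
filed under *A*. The affected taxa then attract each other in trees with
high bootstrap support — an artifact of the gene-family tree, not the
species tree. Shallow libraries (a few thousand reads) make this likely.
Cross-contamination between libraries produces a related artifact: two
taxa sharing near-identical sequences in a partition group together with
a (near-)zero branch between them.

`paraprune` implements a screening workflow for these artifacts, aimed at
people assembling multi-gene amino-acid supermatrices:

1. **Screen** every single-partition ML tree for clades with bootstrap
   support ≥ a threshold (default BP ≥ 95) — suspicious, because
   single-gene support for deep relationships is usually low.
2. **Filter** clades that fall entirely inside a-priori accepted
   monophyletic groups (their support is expected).
3. **Contamination check**: a flagged clade is cross-contamination iff
   (i) some member has a terminal branch ≤ ε (default 10⁻⁶ subst/site)
   and (ii) some member pair is ≥ θ identical (default 0.99) over ≥ 20
   shared alignment columns. Both members of the pair are pruned.
4. **Paralogy check**: best-hit gene labels of the clade members are
   compared with those of the primer taxa (the curated reference species
   of the core ortholog set) against an outgroup transcriptome. Uniform
   labels → no paralogy. A label split → potential paralog: deviating
   sequences are pruned, or — if the primer labels themselves disagree or
   a primer taxon is among the affected sequences — the whole partition
   is excluded.
5. **Prune & concatenate** into the standard dataset family: AD (all
   data), CPr (contamination pruned), CPr*id* (one per paralogy case),
   CPPr (all pruned). Sequence-level pruning keeps columns, so AD and
   CPr have identical lengths; partition exclusion removes columns.

Diagnostics provided alongside: the **branch ratio** (length of the
internal branch leading to a flagged clade divided by the mean of all
internal branch lengths), **leaf stability indices** (LSI, triplet
"maximum" variant) over bootstrap tree sets, and **ΔpsL** — per-site
log-likelihood differences between two topological hypotheses under
LG+Γ+I, summed per partition to localize where a clade's support comes
from.

A seeded synthetic-data module generates gene families with a
pre-speciation duplication, per-branch paralog loss, per-taxon transcript
detection, contaminant transfer between libraries, and an emulator of the
top-down orthology search — with ground truth, so the whole pipeline can
be validated end to end.

## Worked example

The bundled case study transcribes a published screen of an annelid EST
supermatrix (229 partitions, 27 flagged clades). Partition 22433 is its
textbook reciprocal-lack case:

```python
import paraprune as pp
from paraprune.datasets import (PRIMER_TAXA, case_study_clades,
                                case_study_best_hits, branch_profile_tree)

hits = case_study_best_hits()
case = next(c for c in case_study_clades() if c.partition_id == "22433")
clade = case.flagged()

labels = lambda taxa: {t: pp.best_hit_label(hits, t, "22433")[0] for t in sorted(taxa)}
record = pp.assess_paralogy(clade, labels(clade.taxa), labels(PRIMER_TAXA))
action = pp.decide_prune_action(record, PRIMER_TAXA)
diag = pp.branch_diagnostics(branch_profile_tree(case), clade)

print(f"clade {sorted(clade.taxa)} (BP {clade.support})")
print(f"assessment: {record.category}")
print(f"action:     {action.kind} -> {sorted(action.target_taxa)}")
print(f"branch ratio: {diag.branch_ratio:.2f} (leading {diag.leading_branch_length:.4f})")
```

prints

```
clade ['E_complanata', 'S_armiger', 'S_boa'] (BP 100)
assessment: potential_paralog
action:     prune_sequences -> ['E_complanata', 'S_armiger', 'S_boa']
branch ratio: 13.40 (leading 4.1762)
```

Three taxa whose libraries lack PSMA8 were assigned their PSMA2 sequences
instead; the primer taxa all return PSMA8, so only the three deviating
sequences are pruned (the core ortholog set is intact). The branch leading
to the artifact clade is 13.4× the mean internal branch — long, but branch
length alone does not separate paralogy from clean clades, which is why
the label comparison is the decisive evidence.

The same workflow runs from the shell over directories of FASTA
partitions, newick trees and BLAST tabular hits:

```bash
paraprune run --alignments aln/ --trees trees/ --blast hits.tsv \
              --labels accession2gene.tsv --primer-taxa Lg,Ct,Hr --out results/
```

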