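# Frozen vendor dialect grammars

The intake layer recognizes three consumer raw-data dialects plus a generic
fallback. The grammars below are frozen: detection relies only on these
features, and the fixture writers in `dtcprs.genotype_io` emit exactly these
shapes. Real vendors have shipped many minor variants over the years; the
grammar here is the representative common core of each family.

All coordinates are 1-based GRCh37. Allele symbols are `A C G T`; `I`/`D`
insertion-deletion codes are rejected (scoring is SNP-based). Chromosome
labels `1..22, X, Y, MT` (aliases `23→X, 24→Y, 25/26→MT, M→MT`, optional
`chr` prefix).

## 23andMe-style (TSV, `#` comments)

Detected by a comment header naming `rsid/chromosome/.../genotype`, or by
4 tab-separated columns underneath `#` comment lines.

```
# This data file generated by a consumer genotyping service.
# rsid	chromosome	position	genotype
rs1	1	1000	AG
rs2	2	2000	CC
rs3	3	3000	--
```

* `--` = no-call. Single-letter genotypes (haploid X/Y/MT calls) are stored
  as a homozygous pair, PLINK-style.

## AncestryDNA-style (TSV, split allele columns)

Detected by 5 tab-separated columns; the two alleles are merged into one
genotype pair on parsing.

```
rsid	chromosome	position	allele1	allele2
rs1	1	1000	A	G
rs2	2	2000	0	0
```

* `0 0` (or empty alleles) = no-call.

## MyHeritage-style (CSV, quoted fields)

Detected by a comma-separated 4-field layout with quoted fields or an
`RSID,...` header.

```
RSID,CHROMOSOME,POSITION,RESULT
"rs1","1","1000","AG"
"rs2","2","2000","--"
```

## GENERIC fallback

Exactly 4 tab-separated columns (`rsid chrom pos genotype`) with **no**
comment header. Anything else raises `UnrecognizedFormat` — the intake
hard-failure path.

## Shared parsing policy

* malformed lines are counted as rejected with a reason, never fatal;
* duplicate rsids keep the first occurrence (later ones counted rejected);
* an entirely absent autosome raises a `MissingChromosomeWarning`;
* a file with zero valid calls raises `EmptyProfile`.
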