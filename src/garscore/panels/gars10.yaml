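# Ten-gene GARS panel: the nine study genes plus DRD1 (risk 48G).
name: gars10
version: "1.0"
markers:
  - gene: DRD1
    id: rs4532
    class: SNP
    chrom: AUTOSOMAL
    alleles: [48A, 48G]
    risk: [48G]
    note: "-48A/G promoter SNP; regulation of accumbens dopamine release"
  - gene: DRD2
    id: rs1800497
    class: SNP
    chrom: AUTOSOMAL
    alleles: [A2, A1]
    risk: [A1]
    note: "Taq I A1; ANKK1/DRD2 locus; reduced D2 receptor density"
  - gene: DRD3
    id: rs6280
    class: SNP
    chrom: AUTOSOMAL
    alleles: [T, C]
    risk: [C]
    note: "Ser9Gly; C carriers sensitized to cocaine, opioids, alcohol, nicotine"
  - gene: DRD4
    id: DRD4-exon3-VNTR
    class: VNTR
    chrom: AUTOSOMAL
    alleles: [4R, 2R, 3R, 5R, 6R, 7R, 8R, 9R, 10R, 11R]
    risk: {min_repeats: 7}
    note: "48-bp exon III repeat; long (>=7R) allele, novelty seeking / ADHD"
  - gene: MAOA
    id: MAOA-uVNTR
    class: VNTR
    chrom: X_LINKED
    alleles: [3R, 2R, 4R, 5R]
    risk: [4R]
    note: "promoter uVNTR; X-linked, males hemizygous; 4R = fast dopamine catabolism"
  - gene: COMT
    id: rs4680
    class: SNP
    chrom: AUTOSOMAL
    alleles: [A, G]
    risk: [G]
    note: "Val158Met; G = Val = fast synaptic dopamine catabolism"
  - gene: DAT1
    id: DAT1-3UTR-VNTR
    class: VNTR
    chrom: AUTOSOMAL
    alleles: [10R, 3R, 6R, 7R, 8R, 9R, 11R]
    risk: [9R]
    note: "SLC6A3 3'UTR 40-bp VNTR; 9R = fast reuptake (hypodopaminergic)"
  - gene: SLC6A4
    id: 5-HTTLPR
    class: LENGTH_POLYMORPHISM
    chrom: AUTOSOMAL
    alleles: [L, S]
    risk: [S]
    note: "serotonin-transporter-linked promoter length polymorphism; count S not L"
  - gene: OPRM1
    id: rs1799971
    class: SNP
    chrom: AUTOSOMAL
    alleles: [A, G]
    risk: [G]
    note: "A118G; G = Asp40, opiate addiction and pain sensitivity"
  - gene: GABRB3
    id: GABRB3-CA-repeat
    class: LENGTH_POLYMORPHISM
    chrom: AUTOSOMAL
    alleles: [OTHER, "181"]
    risk: ["181"]
    note: "181-bp G1 dinucleotide-repeat allele; anxiety / alcoholism liability"
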