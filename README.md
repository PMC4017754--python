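# g4conserve

Quantitative conservation scoring for putative G-quadruplex motifs across
homologous nucleotide sequences.

G-quadruplexes are four-stranded nucleic-acid structures built from
stacked tetrads of guanines.  Computational scanners find candidate motifs
("QGRS" — quadruplex-forming G-rich sequences) of the form

    G(x) N(y1) G(x) N(y2) G(x) N(y3) G(x)

in vast numbers, far more than can plausibly be functional.  Evolutionary
conservation is a strong filter: a motif preserved — in place *and* in
structure — between, say, a human mRNA and its mouse ortholog is far more
likely to fold and act in the cell.  `g4conserve` is for researchers who
want to rank candidate quadruplexes in mRNA (or DNA) by exactly that
signal without depending on a hosted service.

## The score

For a motif pair across an aligned homolog pair (the *principal* sequence,
typically human, against a *comparison* species), the conservation score
in [0, 1] is the weighted composite

    score = 0.65·overlap + 0.20·tetrad + 0.10·loop + 0.05·length

* **overlap** — the two motif intervals are mapped into the shared frame of
  an end-gap-free (semi-global) affine-gap alignment, padded on each end by
  50 % of the smaller motif's length, and compared as |∩|/|∪|; a step
  function saturates ratios ≥ 0.85 to 1.0 and scales smaller ratios by
  1/0.85.
* **tetrad** — min/max ratio of *fractional* tetrad counts (the tetrad
  count x plus ¼ per G-tract with an adjacent extra guanine); ratios ≤ 0.5
  score 0.  So 3 vs 4 tetrads → 0.75, 2 vs 4 → 0.
* **loop** — mean of the three positionally paired min/max loop-length
  ratios, each zeroed below 0.5.
* **length** — min/max total-length ratio, 0 at ≤ 0.6, linear up to 1.

Scanning reports **all** overlapping motif variants; these are grouped
into *families* (start positions within 5 nt), each family stores the
highest-G-score member as its representative, and a family pair is scored
by the **maximum** composite over the member cross-product — scoring only
the representatives can understate conservation.  Pairs with zero overlap
are discarded automatically.

## Worked example

Two 39-nt homolog fragments that differ only in that the first G-tract of
the quadruplex region is lost in the second sequence:

```bash
printf ">human\nATTACCATTCGGGTGGGTGGGTGGGTGGGCAATCCTAAC\n>mouse\nATTACCATTCCCCTGGGTGGGTGGGTGGGCAATCCTAAC\n" > demo.fasta
g4conserve compare demo.fasta --out-dir demo_out --min-conservation 0.9
```

`demo_out/qgrs_records.csv` holds one row per family representative:

```
sequence_id,family_id,n_members,start_1based,end_1based,tetrads,loop1,loop2,loop3,length,g_score,fractional_tetrads,motif_string
human,1,77,11,25,3,1,1,1,15,39.72222222222222,3.0,GGGTGGGTGGGTGGG
human,2,8,16,29,2,2,2,2,14,19.444444444444443,2.75,GGTGGGTGGGTGGG
```

The human fragment's first family contains 77 overlapping motif variants;
its representative is the 3-tetrad motif at position 11 with single-base
loops (the highest G-score).  `demo_out/conservation_records.csv`:

```
principal_id,comparison_id,principal_family_id,comparison_family_id,overlap,tetrad,loop,length,composite,...
human,mouse,1,1,1.0,1.0,1.0,1.0,1.0,11,15,15,15,GGGTGGGTGGGTGGG,GGGTGGGTGGGTGGG
```

The composite is a perfect 1.0 even though the *representatives* sit at
different positions (human 11, mouse 15): the family cross-product found
the human member at position 15 that mirrors the mouse motif exactly.
Scoring representatives only would have reported ≈ 0.93.

Other entry points: `g4conserve scan` (motif enumeration to CSV, with
optional 5′-UTR/CDS/3′-UTR labels from a CDS-coordinate TSV) and
`g4conserve simulate` (synthetic homolog pairs with planted motifs and a
truth table).  Everything is equally usable as a library:
`find_qgrs`, `semiglobal_align`, `conservation_score`, `group_families`,
`score_family_pair`, `run_pair`.

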