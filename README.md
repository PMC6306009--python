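# cutinseq

De novo sequencing of cutin oligomers from negative-mode tandem mass
spectrometry.

Cutin, the polyester matrix of the plant cuticle, is built from C16/C18
fatty acids decorated with hydroxyl and epoxy groups and cross-linked by
ester bonds.  Partial hydrolysis with a cutinase releases soluble dimers,
trimers and tetramers whose *monomer order* — the "acyl-chain sequence" of
the polymer — can be read from high-resolution MS/MS: ester bonds cleave
under collision to daughter ions whose exact masses identify the monomer
multiset, and the pattern of sub-oligomer daughters fixes which monomer
sits where.  `cutinseq` implements that deduction as a reusable toolkit for
analysts working on cutin, suberin and related polyester lipidomics:

- **exact-mass bookkeeping** for oxygenated fatty-acid monomers
  (`ElementalFormula` arithmetic, adducts `[M-H]-`, `[M+H]+`, `[M+Li]+`,
  `[M+2Li-H]+`, derivatization tags dansyl/benzyl/DmPA);
- a built-in, editable **monomer catalog** for apple cutin with a shorthand
  grammar (`9,10,18-trihydroxy-18:0`) and a one-line symbolic nomenclature
  (`[18:0|COOH@1|OH@9,10,18]`);
- **precursor decomposition** into monomer multisets (complete within a
  mass tolerance; one water per ester bond), **ester-cleavage fragment
  prediction** with serial water losses, and **C-C chain-cleavage
  candidates** that localize mid-chain hydroxyl/epoxy groups;
- an ordering **scorer and ranker** (count of predicted daughters present
  in the spectrum) with explicit ambiguity reporting, central-monomer
  evidence for trimers, and **overlap assembly** of sequenced fragments;
- free-vs-esterified **labeling statistics** (delta-method SE of the log2
  ratio) and internal-standard quantification;
- a seeded **simulator** (polymer → partial digest → noisy spectra) so the
  whole pipeline is testable without instrument data;
- MGF/TSV/CSV/JSON I/O and a `cutinseq` command-line interface.

## The model in brief

An oligomer is an ordered sequence of monomers, index 1 at the free
carboxyl terminus; monomer *i+1* acylates a hydroxyl (by default the
ω-hydroxyl) of monomer *i*.  Its neutral formula is the monomer sum minus
one H₂O per ester bond, and all ion m/z values derive from neutral formulas
plus an adduct — e.g. the dimer of 16-hydroxy-16:0 and
9,10,18-trihydroxy-18:0 gives

  m/z [M−H]⁻ = M(C16H32O3) + M(C18H36O5) − M(H2O) − M(H) = 585.47.

Ester cleavage is modeled as hydrolysis-form fragments on both sides of
each broken bond, each with up to two serial water losses bounded by the
fragment's free-hydroxyl count.  A candidate ordering's score is the number
of predicted daughters matched by observed peaks (10 ppm or 0.02 Da); equal
scores share a rank and are flagged ambiguous — ester-only fragments carry
no direction, so a sequence and its reversal are intrinsically tied unless
other evidence (e.g. end-labeling) breaks the symmetry.

## Worked example

Which monomer pairs explain a dimer precursor at m/z 585.47?

```sh
$ cutinseq decompose --mz 585.47 --max-len 2
composition	theoretical_mz	error_da	error_ppm	isobar
16-hydroxy-16:0+9,10,18-trihydroxy-18:0	585.4730	-0.0030	-5.17	yes
2-hydroxy-16:0+9,10,18-trihydroxy-18:0	585.4730	-0.0030	-5.17	yes
18-hydroxy-18:1+20:3	585.4883	-0.0183	-31.23	no
```

The top pair matches within 5 ppm; the isobar flag warns that a 2-hydroxy
positional isomer is indistinguishable by mass alone.

Sequencing a trimer from its daughter-ion list (precursor m/z 857.65,
daughters 581.44, 563.43, 311.21, 287.22, 293.20, 275.20):

```python
from cutinseq import ADDUCTS, Spectrum, default_catalog, sequence_spectrum

catalog = default_catalog()
spectrum = Spectrum(
    precursor_mz=857.65,
    adduct=ADDUCTS["[M-H]-"],
    peaks=tuple((mz, 1.0) for mz in (581.44, 563.43, 311.21, 287.22, 293.20, 275.20)),
    source_id="trimer",
)
result = sequence_spectrum(spectrum, catalog)
top = result.top
print("top:", " / ".join(top.oligomer.ids))
print("symbolic:", top.symbolic)
print("score:", top.score, " rank:", top.rank, " ambiguous:", result.ambiguous)
ev = result.central_monomer_evidence
print("central:", ev.monomer_id, "via dimers at", ev.dimer_mzs)
```

prints

```
top: 18-hydroxy-9,10-epoxy-18:1 / 10,16-dihydroxy-16:0 / 18-hydroxy-18:3
symbolic: [18:1|COOH@1|OH@18|EP@9-10] <=(18)= [16:0|COOH@1|OH@10,16] <=(16)= [18:3|COOH@1|OH@18]
score: 8  rank: 1  ambiguous: True
central: 10,16-dihydroxy-16:0 via dimers at (581.44, 563.43)
```

Eight predicted daughters are present.  The two dimer daughters (581.44 =
epoxy-18:1 + dihydroxy-16:0 − H₂O; 563.43 = dihydroxy-16:0 +
18-hydroxy-18:3 − H₂O) share the dihydroxy monomer, which therefore
occupies the central position; the `ambiguous` flag records that the
reversed sequence explains the same peaks.

Other entry points: `cutinseq sequence --mgf spectra.mgf` (batch reports in
JSON/CSV), `cutinseq simulate --n 20 --seed 7` (synthetic spectra plus
ground truth), `cutinseq label-ratio --csv observations.csv` (log2
free/esterified ratios ± SE), `cutinseq catalog`, `cutinseq nomenclature`.

## Documentation

See `docs/methods.md` for the full model description: assumptions,
parameter defaults, what the simulator does and does not emulate, numerical
conventions, and known limitations (direction ambiguity, isobars,
regiochemistry).
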