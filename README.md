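# benzilkit

Post-quantum-chemistry analysis for benzil (BZL) and its para-disubstituted
analogues — the dimethyl (DMB), difluoro (DFB), dichloro (DCB) and dibromo
(DBB) diketones. The DFT/TD-DFT calculations themselves are out of scope:
benzilkit starts from their *summaries* (frontier orbital energies, vertical
IP/EA, excitation records, NLO tensors or scalars, vibrational modes and
observed bands, torsional scans, docking score tables) and derives everything
a screening study reports on top of them. It is aimed at computational
chemists who want those derivations reproducible, validated and scriptable
rather than living in a spreadsheet.

## What it computes

**Conceptual-DFT reactivity** (`benzilkit.reactivity`) — from a vertical
(IP, EA) pair: electronegativity χ = (IP+EA)/2, chemical potential μ = −χ,
hardness η = (IP−EA)/2, softness S = 1/η, electrophilicity index
ω = μ²/2η, and the IP−EA gap; plus the frontier-orbital gap
Eg = E(LUMO) − E(HOMO) under a separate name, since the two gaps need not
agree.

**DSSC photovoltaic screening** (`benzilkit.photovoltaics`) — per dye:
light-harvesting efficiency LHE = 1 − 10⁻ᶠ, vertical excitation energy
E(0,0) = 1240/λmax (eV·nm), ground/excited-state oxidation energies
E_dye = −E(HOMO) and E*_dye = E_dye − E(0,0), and the electron-injection
free energy ΔG_inject = E*_dye + E_CB against the TiO₂ conduction band
(E_CB = −4.00 eV by default). More negative ΔG_inject means more spontaneous
injection; `select_best_sensitizer` ranks on it.

**NLO scalars** (`benzilkit.nlo`) — the contracted-vector norm β_total of a
Kleinman-symmetric first-hyperpolarizability tensor, the isotropic
fifth-average of the second hyperpolarizability γ, atomic-unit → esu
conversion, and integer fold-enhancements over a urea reference
(0.13×10⁻³⁰ esu by default).

**Vibrational agreement** (`benzilkit.vibrational`) — harmonic-wavenumber
scaling (factor 0.9613), assigned or nearest-neighbour pairing of calculated
and observed bands, and per-technique RMSD.

**Torsional analysis** (`benzilkit.torsion`) — relative-energy profiles for
the central C4–C6–C5–C3 dihedral, grid-level extrema, barrier heights and
cross-molecule barrier ordering.

**Docking summaries** (`benzilkit.docking`) — validated parsing of ranked
PatchDock-style score tables (global energy, attractive/repulsive vdW,
atomic contact energy), best-complex identification, and the rank-1 ACE
vector that doubles as the QSAR response.

**QSAR** (`benzilkit.qsar`) — the saturated linear model
BE = b₁·IP + b₂·EA + b₃·S + b₄·ω + b₀ per receptor, solved exactly when the
system is square, with conditioning and sign-agreement reporting.

**Synthetic data** (`benzilkit.synthetic`) — seeded generators for every
input kind, with recorded ground truth, so the whole pipeline is testable
offline.

The study inputs (the published tables for the five molecules and the three
receptors 3WMT, 2H4Z, 2EEP) ship as plain-text fixtures under
`benzilkit/data/`.

## Worked example

```python
from benzilkit import load_benzil_series, photovoltaic_table, select_best_sensitizer
from benzilkit.photovoltaics import photovoltaic_record

mols = load_benzil_series()
table = photovoltaic_table(mols)
print(table[["id", "f", "lhe", "e00", "dg_inject"]].round(6).to_string(index=False))
print("best:", select_best_sensitizer([photovoltaic_record(m) for m in mols]))
```

prints

```
 id      f      lhe      e00  dg_inject
BZL 0.6080 0.753396 4.486414  -1.890371
DMB 0.8355 0.853951 4.320708  -1.897185
DFB 0.7299 0.813748 4.561675  -1.766716
DCB 0.9581 0.889871 4.472336  -1.650166
DBB 1.0360 0.907955 4.429204  -1.582816
best: DMB
```

DBB absorbs the most light (LHE 0.908) but DMB has the most negative
injection free energy (−1.897 eV), so DMB is the best sensitizer of the
series. The same chain is available from the shell:

```sh
benzilkit photovoltaics            # screening table + best sensitizer
benzilkit descriptors              # reactivity descriptor table
benzilkit qsar                     # per-receptor fits + printed-coefficient diff
benzilkit reproduce                # re-derive every packaged table and diff
benzilkit make-fixtures --seed 1 --out fixtures/   # synthetic suite
```

`benzilkit reproduce` exits nonzero if any re-derived cell drifts outside
the printed precision of the packaged reference tables.

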