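# siftkin

Post-processing toolkit for the computational characterization of a
protease binding site: **structural interaction fingerprints (SIFt)** over
docked-pose ensembles, **Hill-equation steady-state kinetics**, activity
and purification accounting, and pairwise **sequence identity** — plus a
synthetic-data module that makes the whole pipeline testable without any
external downloads.

## Who it is for

Groups that dock a panel of fluorogenic peptide substrates (X-amc) into a
protease — here the archetype is a hyperthermophilic DJ-1/ThiJ/PfpI-family
cysteine protease with a Cys–His–Glu triad — and then want to answer, from
the pose ensemble and the bench kinetics together:

* Which residues anchor the substrates, and through which interaction
  types, across *all* successfully docked poses (not one cherry-picked
  pose)?
* How do mutant kinetic constants compare with wild type (fold changes in
  k<sub>cat</sub>, K<sub>m</sub>, k<sub>cat</sub>/K<sub>m</sub>)?
* Do the purification and inhibitor/ion panels add up?

## The core methods

**SIFt.** For each docked pose, every contacted receptor residue gets a
9-bit fingerprint — (any, backbone, sidechain, polar, hydrophobic, H-bond
acceptor, H-bond donor, aromatic, charged) — from geometric criteria:
heavy-atom contact ≤ 4.5 Å, donor–acceptor ≤ 3.5 Å (with a ≥120° angle at
the hydrogen when hydrogens are present), ring-centroid π contact ≤ 5.0 Å,
salt bridge ≤ 4.0 Å, polar pair ≤ 3.8 Å. Averaging the bits over an
ensemble of *n* poses gives per-residue interaction *frequencies* — e.g.
"41% of ligands hydrogen-bond to this arginine". Poses are deduplicated
with greedy leader clustering at a 1.0 Å in-place RMSD cutoff (the
AutoDock convention), and binding-site residues are extracted by
thresholding the contact frequency.

**Kinetics.** Initial velocities v(S) are fitted with the Hill equation

&nbsp;&nbsp;&nbsp;&nbsp;v = V<sub>max</sub>·S<sup>h</sup> / (K<sub>m</sub><sup>h</sup> + S<sup>h</sup>)

by nonlinear least squares in log-parameters (h = 1 recovers
Michaelis–Menten; `fix_h=1` pins it). `HillModel(data, enzyme_conc).fit()`
returns a results object with estimates, standard errors,
k<sub>cat</sub> = V<sub>max</sub>/[E]₀, k<sub>cat</sub>/K<sub>m</sub> and a
`summary()` table, statsmodels-style. Helpers compute mutant/WT fold
changes, relative-activity tables (reference = 100%), and purification
tables (specific activity, yield %, fold).

**Sequence identity.** Global (Needleman–Wunsch) alignment with BLOSUM62
and affine gaps (open 10, extend 0.5), identity over aligned columns or
the shorter sequence.

## Worked example

Build a 29-pose synthetic ensemble in which 12 poses hydrogen-bond to
Arg71 and every pose stacks a ring on Tyr120, then average the
fingerprints:

```python
import siftkin as sk

spec = sk.EnsembleSpec(
    planted=(
        sk.PlantedInteraction("hbond_acceptor", residue_name="ARG",
                              residue_number=71, anchor_atom="O",
                              frequency=12/29),
        sk.PlantedInteraction("aromatic", residue_name="TYR",
                              residue_number=120, frequency=1.0),
    ),
    n_poses=29, seed=17, exact=True)
ens = sk.sample_ensemble(spec)
sifts = [sk.compute_sift(ens.receptor, p) for p in ens.poses]
print(sk.average_sift(sifts).to_frame().round(2).to_string())
```

```
             any  backbone  sidechain  polar  hydrophobic  hbond_acceptor  hbond_donor  aromatic  charged
amino_acid
ARG71       0.41      0.41        0.0   0.41          0.0            0.41          0.0       0.0      0.0
TYR120      1.00      0.00        1.0   0.00          1.0            0.00          0.0       1.0      0.0
```

Arg71 is contacted in 12/29 = 41% of poses, always through its backbone,
with a polar H-bond-acceptor contact; Tyr120 interacts with every pose
through sidechain hydrophobic and π–π contacts — the classic signature of
an aromatic gate residue.

Fit noisy synthetic saturation data (k<sub>cat</sub> 0.646 min⁻¹,
K<sub>m</sub> 12 µM at [E]₀ = 1 µM, 3% noise):

```python
kin = sk.KineticsSpec(params=sk.HillParams(0.646, 12.0, 1.0),
                      noise_cv=0.03, seed=42)
res = sk.HillModel(sk.simulate_kinetics(kin), enzyme_conc=1.0).fit()
print(res.summary())
```

```
Hill-equation fit
==============================================
observations: 30   enzyme conc: 1 µM   converged: True
RSS: 0.00173222
----------------------------------------------
parameter           estimate       std err
Vmax                  0.6505      0.004798
Km (µM)                12.42        0.3278
h                     0.9811       0.01922
kcat (min⁻¹)          0.6505      0.004798
kcat/Km              0.05236      0.001089
```

The generating constants are recovered within noise (K<sub>m</sub> 12.42 ±
0.33 µM vs the true 12 µM) and the Hill coefficient sits at 1, as it
should for non-cooperative data.

The same operations are available from the shell (`siftkin sift average`,
`siftkin kinetics fit`, `siftkin purify`, `siftkin seqid`,
`siftkin synth …`); run `siftkin --help`.

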