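# aqpflux

Trajectory analysis for water-channel membrane systems: osmotic permeability
from the collective coordinate of channel water, hydrophobic-mismatch
quantification of the protein-adjacent lipid shell, selectivity-filter pore
geometry, and system-level permeability trend prediction.

It is aimed at molecular-simulation practitioners studying aquaporin–lipid
membranes (e.g. for biomimetic desalination membranes), where the question is
how composition parameters such as the protein–lipid molar ratio shape water
permeability, and whether cheap structural observables can predict it.

## What it computes

**Osmotic permeability.** Water transport through a channel of length *L* is
tracked by the collective coordinate

    dn = Σ_{i ∈ s(t)} dz_i / L,       n(0) = 0,

where *s(t)* is the set of waters inside the channel and *dz_i* their
periodic-boundary-unwrapped z-displacements. A full single-file permeation
changes *n* by exactly ±1. Treating *n(t)* as a 1D random walk, its
diffusivity follows from the Einstein relation ⟨n²(t)⟩ = 2 D_n t: each
channel's series is cut into non-overlapping 200-ps windows, windows from all
channels are pooled into one mean-squared-displacement curve, and D_n is half
the ordinary-least-squares slope. Permeabilities follow by unit conversion,

    p_u,mon = v_w · D_n,        p_u,tet = 4 · p_u,mon,

with v_w ≈ 29.9 Å³ the volume of one water molecule.

**Hydrophobic mismatch.** Bilayer hydrophobic thickness is proxied by the
phosphorus-to-phosphorus distance d_P−P (leaflet-mean z difference). The
deformation imposed by an embedded protein is

    Δd_P−P,adj = d_P−P,origin − d_P−P,deform,

with d_P−P,deform measured on the lipid shell laterally within 5 Å of the
protein and d_P−P,origin on a protein-free reference, both on a five-point,
1-ns block-average schedule.

**Selectivity-filter central area.** Per frame, one representative atom is
picked from each of four pore-lining residues (for aquaporin Z: F43, H174,
T183, R189 — the atom closest to the joint residue centre), the four
positions are projected onto the plane perpendicular to the channel axis, and
the quadrilateral area is computed by angular sort + shoelace formula. The
series is summarised as a relative-frequency histogram (0.5 Å² bins).

**System-level prediction.** With ρ_prot the number of channel proteins per
cm² of membrane, the system permeability trend is ranked by
p_f ∝ ρ_prot / Δd_P−P,adj, and the link p_u,tet ∝ 1/Δd is validated with a
Pearson correlation and its exact two-sided t-test p-value.

Because public trajectory data for such systems is scarce, the package ships
first-class synthetic generators (`aqpflux.synthetic`) that plant known
ground truth for every chain — a closed-form D_n for Brownian channel
waters, an analytic deformation profile for the bilayer, and labelled
two-state dynamics for the filter — so the full pipeline is testable
end-to-end without any download.

## Worked example

Generate a four-channel Brownian water system (8 waters per channel,
D_w = 0.2 Å²/ps, L = 20 Å) and recover its permeability:

```bash
aqpflux synth channel-water --out-dir run --seed 42 --n-frames 200000
python -c "
import json, yaml
t = json.load(open('run/truth.json'))
yaml.safe_dump({'channels': t['channels']}, open('run/channels.yaml', 'w'))"
aqpflux permeability --topology run/topology.pdb --trajectory run/trajectory.dcd \
    --dt 1.0 --channels run/channels.yaml --out-dir run/perm
```

which prints

```json
{
  "D_n_per_ps": 0.003986248825563927,
  "D_n_stderr_per_ps": 6.1905619822199245e-06,
  "v_w_A3": 29.9,
  "p_u_mon_cm3_s": 1.191888398843614e-13,
  "p_u_tet_cm3_s": 4.767553595374456e-13,
  "n_segments": 3996,
  "window_ps": 200.0,
  "fit_range_ps": [0.0, 200.0]
}
```

The fitted D_n = 0.00399/ps sits within 0.4 % of the planted closed form
N_w·D_w/L² = 8·0.2/20² = 0.004/ps; 3,996 pooled 200-ps windows entered the
MSD; p_u,tet is exactly four times the monomer permeability. The same
pattern works for `thickness` (Δd recovery against a protein-free
reference), `filter-area` (bimodal area histogram) and `predict` (ranked
ρ_prot/Δd table plus Pearson statistics); `aqpflux <cmd> --help` lists the
options, and every run writes a `manifest.json` capturing its inputs.

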