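# Methods

## Structure model

`parse_structure` reads PDB-format files (or fetches a 4-character PDB
code from RCSB when a network is available) through Bio.PDB and reduces
the entry to one `StructureModel`: chains of residues with atom
coordinates. Only the first model of multi-model (NMR) entries is kept;
waters are dropped; disordered atoms resolve to their highest-occupancy
conformer; a small alias table renames common non-standard residues
(MSE→MET, SEC→CYS, protonation-state variants of HIS/CYS) and anything
else is dropped with a warning. An amino acid without a Cα cannot be a
network node and is excluded at parse time. Residue identity is
(chain, author residue number, insertion code) throughout; node ids are
`chain:resnum[:icode][:atomrole]`.

## Secondary structure

The contact-energy alphabet needs a 3-state label per residue. When a
DSSP executable is on PATH the 8 DSSP classes are collapsed (H,G,I →
helix; E,B → strand; rest → coil). Otherwise a backbone-dihedral
classifier runs: φ/ψ are computed from N/CA/C coordinates (peptide bonds
longer than 2.5 Å break the chain), and a residue is helix when
φ ∈ [−100°, −30°] and ψ ∈ [−80°, −5°], strand when φ ≤ −90° (or > 160°,
the wrap-around of fully extended chains) and ψ ≥ 90° or < −150°, else
coil. Chain termini, isolated residues and residues with missing backbone
atoms default to coil. The classifier is deterministic and recovers the
generating dihedrals of the synthetic fixtures exactly; on real
structures it is a coarser assigner than DSSP, which is why the DSSP
branch is preferred when available.

## Contact energies

An `EnergyTable` is a symmetric 60×60 matrix over labels `RES_SS`
(e.g. `ALA_H`), validated for completeness, finiteness and symmetry
(tolerance 1e-9). `contact_energy` is a pure lookup on
(type, state) pairs — a property the tests assert by perturbing
coordinates. Candidate contacts are geometric: Cα–Cα distance ≤ 8 Å by
default (inclusive), with an optional minimum-heavy-atom-distance mode;
pairs of the same chain closer than 2 in sequence are excluded, since
covalent neighbours carry no contact information. Both cutoffs and the
exclusion window are configurable.

The packaged default table (`data/mj60_synthetic.tsv`) is a stand-in
constructed from the published Miyazawa–Jernigan (1996) inter-residue
contact energies, replicated across the three secondary-structure states;
its provenance string says so and is copied into every run log. Two
consequences are worth knowing. First, the default carries no real
environment dependence — the three states of a residue type share one
value; the file format supports fully state-resolved tables, and any user
table with the same labelling drops in. Second, the MJ energies are
uniformly attractive, so under the default the `e_ij < 0` rule admits
every candidate contact and the AACEN coincides with the 8 Å distance
graph. Absolute edge sets and residue rankings on real structures
therefore depend on the table supplied; all correctness tests use small
hand-built or seeded toy tables with mixed signs so that nothing in the
package's behaviour is tied to the default's values.

## Builders

AACEN, NACEN and EACEN share one edge rule — candidate contact AND
`e_ij` strictly below the threshold (default 0) — so their edge sets are
identical by construction on identical inputs; the builders differ only
in the attached weights. EACEN edge weights follow the min–max
normalisation of |e| with the floor constant 0.0001 at the minimum;
when all edge energies are equal the range is degenerate and every edge
attains the minimum, so all weights are 0.0001. The normalisation is
implemented literally: an edge with |e| marginally above the minimum can
receive a weight below 0.0001 (no clamping), and the extrema are
per-network, not global constants. EACEN requires a non-positive energy
threshold, since the normalisation is defined for negative energies.

The Cα builder uses a strict `< cutoff` comparison (default 7 Å).
Nucleotides contribute P, C4* and C2 nodes; atoms absent from the
coordinates (typically the 5'-terminal phosphate) are skipped and
counted in the run metadata. The sequence-adjacency exclusion applies
between amino-acid nodes of the same chain only — nucleotide-derived
nodes, including the three nodes of one nucleotide, link purely by
distance, and inter-chain edges are always allowed. Chain breaks do not
suppress edges; only geometry decides.

## Metrics and conventions

Shortest-path computations are delegated to networkx; the test suite
pins them to an independent brute-force all-shortest-paths enumerator
(exhaustive graphs up to 6 nodes, random graphs up to 12) at 1e-9.
Because the AAN literature mixes conventions, the choices here are
explicit and copied into every run log:

* betweenness and edge betweenness are unnormalised, each unordered pair
  counted once;
* closeness(v) = (nodes reachable from v) / (sum of distances from v),
  i.e. an unnormalised inverse average distance; isolated nodes score 0;
* transitivity is the local clustering coefficient, 0 for degree < 2;
* disconnected graphs are handled component-wise (reachable pairs only);
  the diameter is the largest finite eccentricity;
* `L_net` is the mean shortest-path length over connected pairs;
  density is 2m/(n(n−1)); an edgeless network reports L_net = 0.

EACEN path metrics use length = 1/w so strong couplings are short; the
network-level diameter is always computed in hops so it remains an
integer comparable across the four models (the weighted and unweighted
shortest-path trees need not coincide, and a weighted "diameter" in
units of 1/w would not be comparable anyway). Node-weighted NACEN
betweenness/closeness traverse edge lengths (w_i + w_j)/2; this linear
transform is isolated in one function (`to_networkx(lengths=...)`) so an
alternative can be swapped in. It requires strictly positive weights —
Kyte–Doolittle hydrophobicity contains negative values and is therefore
usable as a plain node annotation but rejected for weighted path
metrics, with an explicit error. With uniform weights the transform
assigns unit lengths and the weighted centralities reproduce the
unweighted ones exactly (asserted in the suite). Long-range edges are
those joining different chains/molecules or same-chain amino acids with
sequence separation ≥ 12 (configurable).

## Node weights

Mass (average residue mass, Da), Kyte–Doolittle hydropathy and Grantham
polarity are per-type lookups. Relative solvent accessibility is
structure-dependent: Shrake–Rupley areas (probe 1.4 Å, 960 sphere
points) normalised by the Tien et al. (2013) theoretical maxima and
capped at 1.2, since exposed termini can slightly exceed the
theoretical maximum. Custom weights come from whitespace-separated
`chain resnum weight` lines (`#` comments); a file may cover more
residues than the structure, but every amino-acid node must resolve to
exactly one weight or a `MissingWeightError` lists the gaps.

## Synthetic data

The fixture generator emits PDB text from ideal covalent geometry:
peptide backbones placed atom-by-atom (NeRF) at Engh–Huber bond
lengths/angles with fixed φ/ψ (−57°/−47° helical, 180°/180° extended),
residue types cycling through all 20 amino acids; coarse nucleic strands
on a helical lattice (2.81 Å rise, 32.7° twist) carrying exactly the
P/C4*/C2 representative atoms; two-chain and protein–RNA arrangements
placed so inter-molecular contacts exist at the default cutoffs.
Optional Gaussian coordinate jitter is seeded; identical parameters and
seed give byte-identical text. Toy energy tables are seeded symmetric
60×60 matrices with mixed signs (or all-attractive on request). These
fixtures exercise parsing, classification, contact detection and every
builder, but they are idealised: no side chains, no physical base
pairing, no packing optimisation — so passing tests demonstrate the
correctness of the graph construction and metrics, not the biological
realism of any particular edge set on real structures. Test and
acceptance problem sizes (peptides of 2–20 residues, graphs up to 12
nodes, 20-fixture sweeps) were chosen so the brute-force oracle remains
exact and enumerable.

## Pipelines and outputs

`run_single`/`run_batch` (and the `anca single` / `anca batch` CLI) run
parse → secondary structure → build → metrics → write. Every successful
structure yields six files — labelled adjacency matrix, edge list (with
edge betweenness, long-range flag and raw energies), node list (with all
node metrics and weights), network metrics row, GraphML, and a run log
recording parameters, table provenance and metric conventions — plus a
batch summary with one row per (structure, model). Floats in the
round-trippable exports are written with `repr` so
`read_network(edge_list, node_list)` reconstructs an identical network;
the whole pipeline is deterministic, and repeated runs are byte-identical.
Batch members are processed independently; a failure becomes a
stage-labelled `error:` status row and never aborts the rest.

## Known limitations

* No mmCIF input, NMR ensemble averaging, hydrogen handling or structure
  repair.
* The default energy table is a stand-in (see above); conclusions about
  specific residues on real structures should be drawn with a genuine
  environment-dependent table supplied via `--energy-table`.
* The dihedral secondary-structure classifier is coarser than DSSP near
  irregular geometry; DSSP is preferred automatically when installed.
* Edge construction is residue-level and geometric/energetic only — no
  hydrogen-bond typing, no dynamic (MD-trajectory) networks.
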