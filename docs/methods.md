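# Methods

## Conversion model

A parsed pathway is a mixed graph (`PathwayTopology`): gene nodes with
namespace-tagged native identifiers, compound nodes identifying chemical
entities, group nodes (AND = protein complex, OR = alternative members,
nesting allowed), and typed, optionally directed edges. Conversion to a
genes-only `GeneNetwork` proceeds in four steps, composed by
`converter.convert`:

1. **Compound-subtype splitting** (KGML). A direct protein–protein relation
   annotated with a bridging compound c is replaced by the pair
   `A → c` and `c → B`, each keeping the relation's other subtype names plus
   the marker `indirect (compound split)`. ECrel (enzyme–enzyme via a shared
   compound) follows the same logic and can be disabled
   (`split_compound_subtype(..., include_ecrel=False)`). Without this step
   the compound never enters the graph and the signal through it is
   unrecoverable.

2. **Group expansion.** An AND group links every pair of leaf genes drawn
   from *different* direct children with an undirected `binding` edge; a
   plain AND group of k genes therefore yields the full k(k−1)/2 clique,
   while alternatives collected in a nested OR child are never linked to one
   another (the gamma-secretase case). OR groups add no internal edges.
   Every external edge incident to a group is replicated to all of its
   leaves with direction and types preserved. Groups containing compounds
   are rejected.

3. **Compound propagation.** For every simple path
   `gene A → c1 → … → cm → gene B` (edges ≤ `max_chain_length`, default 10)
   whose interior nodes are all non-blacklisted compounds and whose
   consecutive edges carry the same compartment label at every shared
   compound, the output gains an edge `A → B` typed with the union of the
   first and last hop's types plus `indirect (compound-mediated)`. Each
   distinct chain increments the `ChainHistogram` at its length; multiple
   chains between the same pair merge into one edge. Compound nodes and
   compound-incident edges never reach the output.

4. **Edge merging.** Parallel edges with the same endpoints and
   directedness merge by type-set union, so the result is independent of
   insertion order (exhaustively verified for small edge sets).

### Propagation details

- *Directionality.* An undirected compound-incident edge is traversable both
  ways; the propagated edge is directed iff every hop was directed and
  followed forward. A chain containing an undirected hop therefore yields an
  undirected (bidirectional) gene edge — deliberately more permissive than
  the raw graph's directed reachability.
- *No backtracking.* A chain never traverses the same edge out and straight
  back; otherwise every undirected gene–compound edge would synthesize a
  spurious gene self-loop. Because interior compounds are distinct, this is
  the only possible edge repetition.
- *Compartments.* A missing location is the distinguished label `unknown`,
  which matches only another `unknown` when `require_compartment_match` is
  on (conservative reading of the localization rule). KGML carries no
  location annotation, so all KGML compound occurrences share the default
  label and the rule degenerates to always-true there, as intended.
- *Blacklist.* Matching is case-insensitive over a compound's bare and
  namespace-prefixed identifiers and its display label. The default list
  covers hydrogen ion, water, ATP/ADP, NAD(H), NADP(H), CO2 and phosphate
  (KEGG COMPOUND ids plus common names); it is fully configurable and can
  only shrink the output (adding blacklist entries never adds connections).

## Readers

*KGML*: entries of type `gene`/`ortholog`/`enzyme` with one name become gene
nodes; with several names, an OR group of fresh member nodes (alternative
family members). `group` entries become AND groups over their components.
`map` entries (links to other pathways) are dropped with a log notice, as
are relations touching them. Strict mode raises on unresolvable relation
endpoints; lenient mode skips them with a warning.

*BioPAX* (Level 3; Level 2 property names aliased): one topology per
`pathway` instance, nodes collected through the pathway-component closure.
Complexes are AND groups (recursively); a protein whose reference carries
more than one gene-identifying xref (EntrezGene, HGNC, UniProt, … —
configurable) is an OR group. Occurrences of the same molecule merge by
entity reference, and each occurrence's cellular location lands on the
derived edges so the compartment rule can act. Every conversion yields
left × right `conversion` edges; every control yields controller × right
edges typed `catalysisOut (SIGN)` / `controlOut (SIGN)`.

## Identifier conversion

A 4-column TSV (source namespace/id, target namespace/id) drives
`convert_identifiers`: a node mapping to m targets becomes m nodes inheriting
all incident edges; nodes sharing a target collapse with edge-set union;
self-edges arising purely from a collapse are dropped (pre-existing
self-loops survive); unmapped nodes are removed with a per-node warning.
Dropping unmapped nodes (rather than keeping native ids) keeps the namespace
uniform for downstream topological statistics.

## Perturbation statistic and simulation

`PF = ΔE + B·diag(1/N_ds)·PF` is solved directly (LU), which is exact and
deterministic; genes without upstream edges keep `PF = ΔE`. Edge signs come
from a configurable substring map: inhibition/repression → −1 (checked
first, so a propagated edge whose first hop depletes the bridging compound
is inhibiting), activation/expression → +1, binding/association → 0 (pure
physical association carries no regulatory direction; a nonzero weight
would turn every bare complex clique into a unit-gain feedback loop),
anything else → +1 with a warning. If the system is singular (unit-gain
cycle), the documented fallback multiplies B by a damping factor of 0.99;
the propagation experiment applies one damping to both variants so the
statistic stays comparable.

Because tA = Σ(PF − ΔE) is linear in ΔE, the bootstrap uses a precomputed
weight vector (tA = w·ΔE): the observed non-zero fold changes are reassigned
to genes drawn uniformly without replacement, and
`pPERT = (1 + #{|tA_b − med| ≥ |tA_obs − med|}) / (n_boot + 1)`, recentred on
the null median, never exactly zero, and deterministic given the seed.
Under random DE-gene placement pPERT is approximately U(0,1) (KS-checked in
the tests at 500 replicates).

The propagation-benefit experiment converts one topology twice — full
conversion versus compounds simply deleted — then repeatedly draws
μ_FC ~ U(2, 10) and δ_i ~ N(μ_FC, sd 2) (the sd reading of the dispersion
parameter, following the R `rnorm(mean, sd)` convention) for the designated
genes and computes pPERT on both variants. Designated genes absent from a
variant contribute only where present.

## Synthetic data

The fixture generator emulates the canonical conversion situations with
known ground truth: complex cliques, gene families, compound bridges
(including blacklisted and compartment-mismatched variants), chains of
lengths 2–9, the gamma-secretase complex (three OR groups of 7/2/2 protein
variants plus one plain subunit nested in the AND complex, catalyzing NOTCH1
cleavage), and an insulin-cascade fragment crossing two second messengers,
with PI3K → PDK encoded as a compound-subtype relation and PDE3 ⊣ cAMP → PKA
as explicit protein–compound relations, covering both KGML conventions.
Expected networks are enumerated by hand-written formulas or by an
independent brute-force oracle (exhaustive node-path enumeration plus
per-hop constraint checking), never by the converter under test.

For the simulation study the fragment gains 30 bystander genes in
activation chains of three, giving 45 genes of which the 13 cascade genes
(IR … LIPE) are designated differentially expressed — a desk-scale stand-in
for the full KEGG insulin pathway (~137 genes, 22 DE in the original
design). At 500 replicates and 500 bootstrap resamples the propagated
variant's median pPERT is roughly 0.05 versus 0.70 without propagation,
stable across seeds; only the direction and separation are claims, not the
absolute centers, which depend on network size and DE fraction.

What the fixtures do **not** emulate: real database scale and annotation
noise (thousands of pathways, heterogeneous xref quality), curation
artifacts (dangling references, mixed BioPAX levels in one file),
stoichiometry, and post-translational detail. Passing tests therefore show
the conversion rules are implemented exactly as specified, not that any
particular database snapshot yields particular node/edge counts.

## Numerical and degenerate-input choices

- Chain length is counted in edges, so the single-bridging-compound case is
  length 2 and the default cap of 10 covers the longest chains seen in
  curated databases (9).
- `summarize` uses exact arithmetic on counts (`statistics.fmean`/`median`);
  empty collections are an error rather than NaNs.
- All generators and bootstraps take explicit seeds
  (`numpy.random.default_rng`); identical seeds give byte-identical outputs.
- Degenerate inputs: empty pathway → empty topology; a conversion with an
  empty right side emits nothing; zero DE genes → pPERT = 1; singleton AND
  group → no binding edges.

## Known limitations

- The BioPAX subset ignores stoichiometry, `pathwayStep` ordering and
  template reactions (mapped to the generic conversion rule); there is no
  generic topology → BioPAX writer (the edge → reaction inverse is not
  unique), so only KGML has a full serialize/parse round trip.
- An edge's single compartment field cannot represent a reaction whose two
  compound endpoints sit in different compartments; the source-side label is
  used and a warning logged.
- The perturbation statistic is the topological component only (no
  enrichment term, no cross-pathway FDR), matching its role here of
  quantifying the effect of propagation on one network.
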