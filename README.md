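# synkaryo

Comparative genetic-map analysis of chromosomal rearrangements.

Given per-species genetic maps (marker order in cM), a 1:1 marker
orthology table and a dated phylogeny, `synkaryo`:

* projects every species map onto a common reference map (rank-based, so
  incompatible cM scales never matter);
* partitions chromosomes into reference-painted **segments**, yielding
  translocation junctions with flanking-marker breakpoint regions,
  including embedded (excision/insertion) patterns;
* detects **inversions** inside each segment from the rank order, with
  confidence flags for two-marker flips and "k+" lower bounds where
  stacked inversions cannot be separated at marker resolution;
* places every event on a branch of the dated tree by two-state
  **parsimony** (the reference species is not privileged: an event shared
  by all other species lands on the reference's own terminal branch), or
  reports an explicit candidate branch set when outgroups are
  uninformative;
* reconstructs **ancestral karyotypes** chromosome by chromosome, with
  explicit unknown/partially-resolved states;
* estimates per-branch **rearrangement rates** (events/MY, with min--max
  ranges from undetermined events) and detects **breakpoint reuse**
  (independent translocations with intersecting breakpoint intervals,
  flagged for centromere proximity);
* **simulates** marker-map evolution (Poisson inversions/translocations,
  per-species marker dropout, optional breakage hotspots) and emits the
  true history, which serves as the oracle for the whole pipeline.

A bundled observation set for five Solanaceae species (tomato, potato,
eggplant, pepper, *Nicotiana*) over the dated tree
`((((tomato,potato)ATPt,eggplant)ATE,pepper)ATP,nicotiana)ATN`
exercises the timing, rate and reuse machinery end to end.

## Command line

```sh
synkaryo fixture  --out fx/                      # write the bundled dataset
synkaryo load     --maps fx/ --orthology o.tsv --tree t.nwk --config ages.yaml
synkaryo segment  --maps DIR --orthology o.tsv --species eggplant --reference tomato
synkaryo inversions --maps DIR --orthology o.tsv --species pepper --reference tomato
synkaryo time     --observations fx/solanaceae_observations.tsv \
                  --tree fx/solanaceae_tree.nwk --config fx/solanaceae_config.yaml
synkaryo ancestors --node ATE --observations ... --tree ... --config ...
synkaryo rates    --observations ... --tree ... --config ...
synkaryo reuse    --observations ... --centromeres fx/solanaceae_centromeres.tsv \
                  --reference-map fx/solanaceae_reference_map.tsv
synkaryo simulate --config sim.yaml --seed 42 --out sim/
```

File formats are plain TSV (maps: `species chromosome marker position_cM
confidence`; orthology: `group_id species marker`; observations: one row
per event with per-species `R`/`E`/`U` state columns), Newick for the
tree and YAML for node ages.

## Layout

```
src/synkaryo/
  map_model_io.py        maps, orthology, dated tree, reference projection
  segmentation.py        segments + translocation junctions
  inversion_detect.py    inversion calling within segments
  timing_parsimony.py    comparison rules + branch assignment + counting
  ancestral_karyotype.py rule-based ancestral reconstruction + rendering
  rates_reuse.py         rate estimation, breakpoint-reuse detection
  synthetic_data.py      seeded simulator + bundled fixture
  pipeline.py            end-to-end driver + truth-evaluation harness
  data/                  bundled Solanaceae observation set (TSV/Newick/YAML)
tests/                   pytest suite; test_acceptance.py holds the
                         acceptance criteria (criterion 5 runs 200 seeded
                         simulations, ~10 s)
```
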