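# kweb — keystone species identification in quantitative food webs

`kweb` finds the species whose loss does the most structural damage to a
flux-weighted food web.  It is aimed at ecologists working with
quantitative (carbon-flux) food webs — the kind distributed with
ecological network analysis collections — who want to rank species, or
*sets* of species, by how many secondary extinctions their removal would
trigger.

## The model

A quantitative food web is a directed network *G* = (*V*, *E*) whose
edge weights *w<sub>ij</sub>* are energy fluxes (gC·m⁻²·day⁻¹), plus
per-species imports, exports and respiration.  A virtual environment
node feeds every importing species and absorbs outflows; it is never
removable.

**Extinction cascade.**  Removing a species deletes all its edges.
Each remaining species *i* is judged by the fraction of its original
inflow it still receives,

P(*i*) = Σ<sub>j alive</sub> *w′<sub>ji</sub>* / Σ<sub>j</sub> *w<sub>ji</sub>*,

and goes extinct secondarily when P(*i*) ≤ *t*, where *t* ∈ [0, 1] is the
extinction threshold.  Extinctions propagate to a fixed point, which is
unique because the cascade is monotone.

**Objective.**  A removal strategy is a binary vector
*X*<sub>ind</sub> = [*x*₁ … *x*<sub>N</sub>] with Σ*x*ᵢ = *N* − *n*; its
disintegration is *F*(*X*<sub>ind</sub>) = *f*(*G*₀) − *f*(*G*), the
number of species lost (primary + secondary).  The keystone set of size
*n* maximises *F*.  Exhaustive search costs C(*N*, *n*) cascade
evaluations, so `kweb` optimises with **tabu search**: a swap
neighbourhood (exchange one removed with one kept species), a FIFO tabu
list of recent swaps to prevent cycling, and an aspiration rule that
clears the list whenever the best-so-far solution improves.

**Evaluation.**  Removal protocols are summarised by the secondary
extinction curve *N<sub>p</sub>* (total extinctions after *p* primary
removals), its area above the 1:1 line
SEA = (Σ<sub>p</sub> *N<sub>p</sub>*)/*N*² − 0.5, and the robustness
*R*₅₀ — the minimum fraction of primary removals that kills at least
half the species.  Five flux-weighted centrality baselines (out-degree
OD, in-degree ID, their sum SD and product PD, and eigenvector
centrality EIG) are provided for comparison, along with a harness that
runs all six strategies over many webs and tests the differences with a
one-way ANOVA and Dunnett many-to-one contrasts against the tabu-search
control.

## Worked example

Generate a 25-species synthetic web (niche-model topology, lognormal
fluxes), summarise it, and ask for the most destructive 3-species set at
threshold 0.5:

```sh
$ kweb synth --S 25 --C 0.15 --seed 7 --out web.json
$ kweb info web.json
{
 "name": "niche_S25_C0.15_seed7",
 "S": 25,
 "C_n": 89,
 "C": 0.142,
 "C_w": 0.107
}
$ kweb tabu web.json --n 3 --t 0.5 --tmax 100 --ncan 20 --L 7 --seed 1
{
 ...
 "best_set": ["sp002", "sp003", "sp006"],
 "F": 20,
 "trace": [8, 13, 15, 15, 15, 17, ...]
}
```

Removing the three species found by the search wipes out 20 of the 25
species (3 primary + 17 secondary extinctions); the trace shows the
best-so-far objective climbing across iterations.  Removal *curves*
make the contrast with a centrality baseline explicit:

```sh
$ kweb curve web.json --method TS --t 0.5 --tmax 30 --ncan 8 --L 3 --seed 1 --out ts.tsv
$ kweb curve web.json --method ID --t 0.5 --out id.tsv
```

On this web the tabu-search protocol reaches SEA = 0.425 and
R₅₀ = 0.080, against SEA = 0.121 and R₅₀ = 0.440 for in-degree removal:
the optimizer needs 2 primary removals to halve the web where the
in-degree ranking needs 11.

Other subcommands: `kweb cascade` (one explicit removal set),
`kweb sequence` (step-by-step centrality protocol), `kweb sweep`
(threshold grid), `kweb compare` / `kweb stats` (multi-web comparison
with ANOVA + Dunnett report).  Library use mirrors the CLI:
`kweb.tabu_search_optimize`, `kweb.simulate_cascade`, etc.

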