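# antagosim

Simulations of how multiple antagonists (phage- or plasmid-like parasites)
jointly affect the composition of a competitive microbial community.

A community of `n` focal species follows competitive Lotka–Volterra dynamics

```
dx_i/dt = r_i * x_i * (1 - sum_j alpha[i, j] * x_j)
```

with a random interaction matrix: focal–focal off-diagonals are
Uniform(0, A/n), `m` antagonists impose half-normal(σ) per-capita costs on
each focal species, antagonists are insensitive to focal densities, and all
self-interactions and antagonist–antagonist interactions equal 1.  Every
replicate integrates the same focal draw twice — with and without its
antagonists — and scores the two focal relative-abundance vectors with
Bray–Curtis dissimilarity and Kendall rank correlation.  A sweep engine
aggregates paired replicates into per-tile means over a `(n, m, σ, A)` grid.

Closed-form companions (half-normal moments, the 1/√m decay of the
coefficient of variation of the combined antagonist effect, symmetric-community
equilibria) are implemented as oracles, alongside Shannon diversity and
Pielou evenness.

## Layout

| module | contents |
| --- | --- |
| `antagosim.model` | `CommunitySpec`, random matrix/growth-rate assembly, ODE right-hand side |
| `antagosim.dynamics` | adaptive RK 5(4) integration (numba-compiled), Euler reference, composition readout |
| `antagosim.metrics` | Bray–Curtis, Kendall rank correlation (tau-a and a literal `(nc-nd)/n` variant), Shannon H, evenness J |
| `antagosim.analytic` | half-normal moments, CV of the combined effect, symmetric equilibria |
| `antagosim.sweep` | paired with/without-antagonist runs, tile aggregation, counter-based seeding |
| `antagosim.io_cli` | YAML config, tile-table CSV I/O, fixture registry, CLI |

## CLI

```bash
# one community: densities + focal composition as JSON
antagosim simulate --n 10 --m 5 --sigma 0.3 --a 0.5 --seed 1

# paired sweep over a grid described in YAML -> tile CSV
antagosim sweep --config config.yaml --out tiles.csv --seed 1 --replicates 2000

# closed-form CV of the combined antagonist effect
antagosim cv --sigma 0.3 --m-max 10

# Shannon diversity and evenness of a composition
antagosim diversity 0.5 0.25 0.25
```

A minimal sweep config:

```yaml
n_values: [10]
m_values: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
sigma_values: [0.3]
A_values: [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
replicates: 2000
root_seed: 1
```

Defaults (logged at load time): `t_end: 1000`, `rel_tol`/`abs_tol: 1e-8`,
`convergence_tol: 1e-6`, `readout_floor: 1e-12`, `initial_density: 0.1`,
`kendall_variant: standard_tau_a`, `pairing_mode: paired`.  Seeding is
counter-based per (tile, replicate), so serial and parallel (`--jobs`)
execution produce byte-identical CSVs.

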