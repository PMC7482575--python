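# netflock

Simulation toolkit for studying how the **structure of a fixed interaction
network** shapes self-organized collective motion. It implements two
minimal flocking models on identical footing —

* the **Vicsek-Network (VN)** model, a velocity-based heading-consensus
  rule: `θ_i(t+1) = Angle[Σ_{j∈S_i∪{i}} n̂_j(t)] + η ξ_i(t)`, with
  `ξ_i ~ U(−½, ½)` and noise intensity `η ∈ [0, 2π]`;
* the **Active-Elastic (AE)** model, a position-based mechanism in which
  agents never exchange headings but are coupled by linear springs:
  `ẋ_i = v0 n̂_i + α (F_i·n̂_i) n̂_i`, `θ̇_i = β (F_i·n̂_i⊥) + η ξ_i`, with
  `F_i = κ Σ_j (‖r_ij‖ − l_ij) r̂_ij`, integrated by forward Euler —

and the network machinery to interpolate, at constant node count `N = L²`
and edge count `K = 2(L−1)(2L−1)`, between a nearest-neighbour lattice
(each agent linked to its ≤8 Moore neighbours), Erdős–Rényi random graphs,
and scale-free random graphs whose degree histogram follows a truncated
integer power law `n_k = Round(C k^b)`, `k ≥ 2`. A superposition parameter
`p ∈ [0, 1]` mixes lattice and random edge sets (`p = 0` pure lattice,
`p = 1` pure random network).

The headline observable is the polarization order parameter
`ψ = |Σ_i n̂_i| / N` and the **critical noise η_c** at which the ordered
state is lost: estimated from the variance peak of ψ (VN, continuous
transition, parabolic interpolation through the three top grid points) or
from the loss of the ordered branch (AE, discontinuous transition,
midpoint of the bracketing noise values). The interesting physics is that
random long-range links always *increase* η_c for heading-consensus
dynamics, while for spring-based dynamics an overabundance of weakly
constrained low-degree agents (scale-free topologies, steep exponents) can
*decrease* it.

Audience: active-matter and collective-behaviour researchers, and swarm
robotics engineers choosing communication topologies.

## Worked example

```python
import numpy as np
import netflock as nf

# a 9x9 lattice: 81 agents, 272 links (corners 3, sides 5, bulk 8)
positions, nn = nf.build_nn_lattice(nf.LatticeSpec(9))
print(nn.n_edges, nf.degree_histogram(nn).counts)
# 272 {3: 4, 5: 28, 8: 49}

# a scale-free partner with the same N and K, exponent b = -2
seq = nf.solve_sf_degree_sequence(nf.SFDegreeModel(N_tgt=81, K_tgt=272, b=-2))
print(seq.n_nodes, seq.degree_sum)          # 81 544  (= 2K, handshake)
sf = nf.realize_degree_sequence(seq, seed=1)

# half-way superposition keeps K fixed
mix = nf.superpose(nn, sf, p=0.5, seed=2)
print(mix.n_edges, nf.is_connected(mix))    # 272 True

# VN dynamics from the aligned state
state = nf.init_aligned(81, np.pi / 2)
psi, _ = nf.run_model("vn", mix, nf.VNParams(eta=2.0), 2000, seed=3,
                      initial_state=state)
print(round(nf.stationary_mean(psi, 0.5), 3))   # 0.807

# critical noise from a sweep (variance-peak criterion)
sweep = nf.bifurcation_sweep("vn", nf.TopologySpec(family="nn2sf", L=9, p=0.5),
                             np.linspace(1.0, 5.5, 10), runs=6, steps=4000,
                             seed=4)
print(round(nf.estimate_eta_c(sweep, "variance_peak").eta_c, 3))  # 4.09
```

The numbers mean: the 81-agent mixed topology holds strong alignment
(ψ ≈ 0.81) at η = 2.0, and its order–disorder transition sits near
η_c ≈ 4.1 at this (small, finite-size-inflated) system size.

The same workflows are scriptable from the shell:

```bash
netflock netgen --family nn --L 9 --out nn9.edges     # 272-line edge list
netflock simulate --model ae --eta 0 --steps 100 --L 9 --out psi.csv
netflock sweep --model vn --family nn2er --L 32 --p 0.5 \
    --eta-min 1 --eta-max 5.5 --eta-num 12 --runs 8 --steps 20000 \
    --seed 0 --out sweep.csv
netflock critical --input sweep.csv
netflock experiment ae_critical --family nn2sf --scale small --seed 0 --out-dir out/
```

`--scale full` switches the presets to the complete 100×100 protocol
(hours-to-weeks of CPU; the default `small` scale is a 32×32 system with
shortened runs).

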