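# memodyn

Adaptive dynamics of memory-one strategies in the repeated donation game.

## The problem

In the donation game, two players repeatedly choose to cooperate (pay a cost
*c* to give the partner a benefit *b*, with *b* > *c* > 0) or to defect.  The
one-round payoffs are (R, S, T, P) = (b−c, −c, b, 0), a prisoner's dilemma
with "equal gains from switching" (R + P = T + S).  A **memory-one strategy**
is a point **p** = (p_CC, p_CD, p_DC, p_DD) ∈ [0,1]⁴: the probability of
cooperating after each joint outcome of the previous round (the focal
player's move listed first).  Two memory-one players generate a Markov chain
over {CC, CD, DC, DD}; long-run payoffs A(**p**, **p′**) are averages under
its stationary distribution, computable in closed form by the Press–Dyson
determinant quotient.

**Adaptive dynamics** models a homogeneous population that moves in the
direction of the invader-payoff gradient,

&nbsp;&nbsp;&nbsp;&nbsp;ṗᵢⱼ = ∂A(**p′**, **p**)/∂p′ᵢⱼ |_{**p′**=**p**} ,

defining a flow on the strategy cube.  Multiplying by the positive factor
(1 − p_CD + p_DC)·r(**p**)² turns the gradient into a polynomial vector
field with the same orbits — total on the closed cube, which is what makes
boundary analysis and exhaustive grid censuses possible.  The package
implements this machinery for researchers in evolutionary game theory and
direct reciprocity:

* exact payoffs for memory-one, counting, and memory-n strategies
  (determinant and stationary-distribution forms, cross-checked);
* the closed-form rescaled fields on the memory-one 4-cube and on the
  3-cube of **counting strategies** (p_CD = p_DC — strategies that only
  count how many players cooperated last round), which form an invariant
  subspace;
* the forward/backward orbit duality σ(**p**) = (1−p_DD, 1−p_DC, 1−p_CD,
  1−p_CC), the
  interior critical plane/line (= the equalizer strategies, which force
  every opponent to the same payoff), eigenvalue classification of the
  critical line, and boundary-saturation analysis including the cooperative
  Nash set on the face p_CC = 1;
* trajectory integration with boundary stopping and endpoint
  classification, and the sign / endpoint / cooperative-region grid
  censuses, also exposed as a `memodyn` command-line tool.

## Worked example

```python
import numpy as np
import memodyn as md

game = md.GamePayoffs.donation(b=1.0, c=0.1)

# an interior critical point of the dynamics with (p_CD, p_DC) = (0.5, 0.5)
p = md.critical_plane_point(0.5, 0.5, game)
print(p)                                # [0.59090909 0.5  0.5  0.40909091]
print(md.memone_field(p, game))         # ~[0 0 0 0] — a rest point

# critical points are equalizers: every opponent earns the same payoff
print(md.payoff(md.TFT,  p, game))      # 0.450000
print(md.payoff(md.ALLD, p, game))      # 0.450000

# directional census of the field on the 9-per-axis interior grid
sc = md.sign_census(md.GridSpec(9, 4), game)
print(sc.tally["++++"], sc.tally["----"], sc.tally["0000"])
# 1424 3267 8

# a counting-strategy trajectory with non-monotone cooperation
out = md.integrate(np.array([0.6, 0.5, 0.0]), "counting", game)
cs = md.cooperation_series(out, game)
print(out.endpoint_class, round(cs[-1], 3))   # full_cooperation 1.0

# stability type on the interior critical line
print(md.classify_critical(0.3, game).label)  # sink
```

The equalizer at (0.5909, 0.5, 0.5, 0.4091) pins every opponent to payoff
0.45 = (b−c)/2; the sign census shows 1424 of 6561 grid strategies with all
four cooperation probabilities locally increasing, 3267 with all four
decreasing, and 8 exact rest points; the trajectory from (0.6, 0.5, 0)
raises the population's self-cooperation rate from 0 to an intermediate
value, dips, and then climbs to full cooperation.

The same censuses from the shell:

```bash
memodyn sign-census --grid-n 9 --space memone --out sign.json
memodyn endpoint-census --grid-n 9 --space counting --out endpoints.csv --format csv
memodyn classify-line --cost 0.3 --resolution 101 --out line.csv --format csv
memodyn trajectory --start 0.6,0.5,0 --out traj.csv --format csv
```

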