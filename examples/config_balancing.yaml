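# Complete annotated model configuration for the sdturnover CLI.
# Any key can be overridden on the command line, e.g.
#   sdturnover phi-ode --config examples/config_balancing.yaml --r 0.005 --grid 0.05:0.95:19
#   sdturnover simulate --config examples/config_balancing.yaml --p0 0.5 --reps 20000 --seed 1

N: 10000      # diploid population size
r: 0.0        # recombination fraction between the A/a and B/b loci per meiosis
case: 1       # 1 = masculinizing A (male heterogamety retained); 2 = strongly feminizing A
s_m: 0.02     # selection coefficient of allele B in males  (case 1 needs s_m >= 0)
s_f: -0.02    # selection coefficient of allele B in females (case 1 needs s_f <= 0)
h_m: 1.0      # dominance of B in males, in [0, 1]
h_f: 0.0      # dominance of B in females  (this scheme: balancing selection, p* = 0.5)
u: 1.0e-6     # mutation rate B -> b per generation
v: 1.0e-6     # mutation rate b -> B per generation
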