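64
Lattice="10.820000 0.0 0.0 0.0 15.301791 0.0 0.0 0.0 7.650895" pbc="T T F"
Zn        5.41000000      3.82544769      0.00000000
Zn        0.00000000      3.82544769      0.00000000
Zn        5.41000000      0.00000000     -0.00000000
Zn        8.11500000     13.38906690      1.91272384
Zn        8.11500000      1.91272384      1.91272384
Zn        5.41000000      0.00000000      3.82544769
Zn        0.00000000      0.00000000     -0.00000000
Zn        2.70500000     13.38906690      1.91272384
Zn        2.70500000      1.91272384      1.91272384
Zn        0.00000000      0.00000000      3.82544769
Zn        5.41000000     11.47634306     -0.00000000
Zn        0.00000000     11.47634306     -0.00000000
Zn        5.41000000      7.65089537      0.00000000
Zn        8.11500000      5.73817153      1.91272384
Zn        8.11500000      9.56361922      1.91272384
Zn        5.41000000      7.65089537      3.82544769
Zn        0.00000000      7.65089537      0.00000000
Zn        2.70500000      5.73817153      1.91272384
Zn        2.70500000      9.56361922      1.91272384
Zn        0.00000000      7.65089537      3.82544769
Zn        5.41000000      3.82544769      3.82544769
Zn        8.11500000      1.91272384      5.73817153
Zn        8.11500000      5.73817153      5.73817153
Zn        0.00000000      3.82544769      3.82544769
Zn        2.70500000      1.91272384      5.73817153
Zn        2.70500000      5.73817153      5.73817153
Zn        5.41000000     11.47634306      3.82544769
Zn        8.11500000      9.56361922      5.73817153
Zn        8.11500000     13.38906690      5.73817153
Zn        0.00000000     11.47634306      3.82544769
Zn        2.70500000      9.56361922      5.73817153
Zn        2.70500000     13.38906690      5.73817153
S         9.46750000      1.91272384     -0.00000000
S         9.46750000      5.73817153      0.00000000
S         6.76250000      3.82544769      1.91272384
S         4.05750000      1.91272384     -0.00000000
S         4.05750000      5.73817153      0.00000000
S         1.35250000      3.82544769      1.91272384
S         6.76250000      0.00000000      1.91272384
S         9.46750000     13.38906690      3.82544769
S         9.46750000      1.91272384      3.82544769
S         6.76250000      0.00000000      5.73817153
S         1.35250000      0.00000000      1.91272384
S         4.05750000     13.38906690      3.82544769
S         4.05750000      1.91272384      3.82544769
S         1.35250000      0.00000000      5.73817153
S         9.46750000      9.56361922     -0.00000000
S         9.46750000     13.38906690      0.00000000
S         6.76250000     11.47634306      1.91272384
S         4.05750000      9.56361922     -0.00000000
S         4.05750000     13.38906690      0.00000000
S         1.35250000     11.47634306      1.91272384
S         6.76250000      7.65089537      1.91272384
S         9.46750000      5.73817153      3.82544769
S         9.46750000      9.56361922      3.82544769
S         6.76250000      7.65089537      5.73817153
S         1.35250000      7.65089537      1.91272384
S         4.05750000      5.73817153      3.82544769
S         4.05750000      9.56361922      3.82544769
S         1.35250000      7.65089537      5.73817153
S         6.76250000      3.82544769      5.73817153
S         1.35250000      3.82544769      5.73817153
S         6.76250000     11.47634306      5.73817153
S         1.35250000     11.47634306      5.73817153
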