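5852bf5cac99bc29e9dccd841ca38cc987e84d009013799454b483eed7fdb9b3  table1_diurnal.csv
1d7b8288bfd2f2f3427dfe66749990e20ab3149c451984a27549e20a08b180d5  table2_light_response.csv
d6941cd83e9f279802fc7d4c03ac2e5dd92834cc18a4c8e1a14e29d05f00cbc3  table4_co2_response.csv
4a13d7dc1f6bfb236d1ce1381f784d6d2a667b1077fe5b8e20cffec42d0b9f6c  table5_slow_kinetics.csv
7845bb4f8b2c224599078c0619e82b69647d861f866335ec2f2c438cf0181385  table5_rlc.csv
840bb2840165cef3dd0921e2e5709e46882f99e25c43c4cb122486fde36e2354  table3_reference.json
c274435485c9cac50562cf47f4541484111f186222f2e2c185985b5aeda53e4e  table6_reference.json
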