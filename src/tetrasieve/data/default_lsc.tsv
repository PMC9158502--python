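# provenance: tetrasieve calibrate --sim-genomes 8 --sim-length 1100000 --sim-components 3 --bins 10:200:10 --pairs 200 --seed 42
kb	mean_intra	sd_intra	n_samples
10	0.9864120159709836	0.0277772398679094	200
20	0.9824454898532752	0.0276697040560526	200
30	0.973524408134504	0.0377294826212534	200
40	0.9811138289340384	0.0341000817958832	200
50	0.9872584533715328	0.0352945354767796	200
60	0.987220663165982	0.023474572876621	200
70	0.9907891278583372	0.0183457744648995	200
80	0.989805402771036	0.0201048335555539	200
90	0.9922426033545132	0.013938259774905	200
100	0.98972305925116	0.0221071864824386	200
110	0.9877615889260146	0.0215191062082644	200
120	0.9851315973938009	0.0216794443577264	200
130	0.9889508186722016	0.0151059660291085	200
140	0.9968854187111804	0.0038359981212357	200
150	0.9997293197970398	0.0002205436774425	200
160	0.9979646179243948	0.002768544548869	200
170	0.9937026112617744	0.0082144271318184	200
180	0.993315960726558	0.0100478875421887	200
190	0.9950739253170864	0.0087339071023718	200
200	0.9966106297612614	0.0066713392891109	200
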