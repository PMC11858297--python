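taxon_id	lineage
ASV_0001	Phylum_A;Class_0;Order_0;Family_0;ASV_0001_genus
ASV_0002	Phylum_A;Class_1;Order_1;Family_1;ASV_0002_genus
ASV_0003	Phylum_A;Class_2;Order_2;Family_2;ASV_0003_genus
ASV_0004	Phylum_B;Class_0;Order_0;Family_0;ASV_0004_genus
ASV_0005	Phylum_B;Class_1;Order_1;Family_1;ASV_0005_genus
ASV_0006	Phylum_B;Class_2;Order_2;Family_2;ASV_0006_genus
ASV_0007	Phylum_C;Class_0;Order_0;Family_0;ASV_0007_genus
ASV_0008	Phylum_C;Class_1;Order_1;Family_1;ASV_0008_genus
ASV_0009	Phylum_C;Class_2;Order_2;Family_2;ASV_0009_genus
ASV_0010	Phylum_D;Class_0;Order_0;Family_0;ASV_0010_genus
ASV_0011	Phylum_D;Class_1;Order_1;Family_1;ASV_0011_genus
ASV_0012	Phylum_D;Class_2;Order_2;Family_2;ASV_0012_genus
ASV_0013	Phylum_A;Class_0;Order_0;Family_0;ASV_0013_genus
ASV_0014	Phylum_A;Class_1;Order_1;Family_1;ASV_0014_genus
ASV_0015	Phylum_A;Class_2;Order_2;Family_2;ASV_0015_genus
ASV_0016	Phylum_B;Class_0;Order_0;Family_0;ASV_0016_genus
ASV_0017	Phylum_B;Class_1;Order_1;Family_1;ASV_0017_genus
ASV_0018	Phylum_B;Class_2;Order_2;Family_2;ASV_0018_genus
ASV_0019	Phylum_C;Class_0;Order_0;Family_0;ASV_0019_genus
ASV_0020	Phylum_C;Class_1;Order_1;Family_1;ASV_0020_genus
ASV_0021	Phylum_C;Class_2;Order_2;Family_2;ASV_0021_genus
ASV_0022	Phylum_D;Class_0;Order_0;Family_0;ASV_0022_genus
ASV_0023	Phylum_D;Class_1;Order_1;Family_1;ASV_0023_genus
ASV_0024	Phylum_D;Class_2;Order_2;Family_2;ASV_0024_genus
ASV_0025	Phylum_A;Class_0;Order_0;Family_0;ASV_0025_genus
ASV_0026	Phylum_A;Class_1;Order_1;Family_1;ASV_0026_genus
ASV_0027	Phylum_A;Class_2;Order_2;Family_2;ASV_0027_genus
ASV_0028	Phylum_B;Class_0;Order_0;Family_0;ASV_0028_genus
ASV_0029	Phylum_B;Class_1;Order_1;Family_1;ASV_0029_genus
ASV_0030	Phylum_B;Class_2;Order_2;Family_2;ASV_0030_genus
ASV_0031	Phylum_C;Class_0;Order_0;Family_0;ASV_0031_genus
ASV_0032	Phylum_C;Class_1;Order_1;Family_1;ASV_0032_genus
ASV_0033	Phylum_C;Class_2;Order_2;Family_2;ASV_0033_genus
ASV_0034	Phylum_D;Class_0;Order_0;Family_0;ASV_0034_genus
ASV_0035	Phylum_D;Class_1;Order_1;Family_1;ASV_0035_genus
ASV_0036	Phylum_D;Class_2;Order_2;Family_2;ASV_0036_genus
ASV_0037	Phylum_A;Class_0;Order_0;Family_0;ASV_0037_genus
ASV_0038	Phylum_A;Class_1;Order_1;Family_1;ASV_0038_genus
ASV_0039	Phylum_A;Class_2;Order_2;Family_2;ASV_0039_genus
ASV_0040	Phylum_B;Class_0;Order_0;Family_0;ASV_0040_genus
ASV_0041	Phylum_B;Class_1;Order_1;Family_1;ASV_0041_genus
ASV_0042	Phylum_B;Class_2;Order_2;Family_2;ASV_0042_genus
ASV_0043	Phylum_C;Class_0;Order_0;Family_0;ASV_0043_genus
ASV_0044	Phylum_C;Class_1;Order_1;Family_1;ASV_0044_genus
ASV_0045	Phylum_C;Class_2;Order_2;Family_2;ASV_0045_genus
ASV_0046	Phylum_D;Class_0;Order_0;Family_0;ASV_0046_genus
ASV_0047	Phylum_D;Class_1;Order_1;Family_1;ASV_0047_genus
ASV_0048	Phylum_D;Class_2;Order_2;Family_2;ASV_0048_genus
ASV_0049	Phylum_A;Class_0;Order_0;Family_0;ASV_0049_genus
ASV_0050	Phylum_A;Class_1;Order_1;Family_1;ASV_0050_genus
ASV_0051	Phylum_A;Class_2;Order_2;Family_2;ASV_0051_genus
ASV_0052	Phylum_B;Class_0;Order_0;Family_0;ASV_0052_genus
ASV_0053	Phylum_B;Class_1;Order_1;Family_1;ASV_0053_genus
ASV_0054	Phylum_B;Class_2;Order_2;Family_2;ASV_0054_genus
ASV_0055	Phylum_C;Class_0;Order_0;Family_0;ASV_0055_genus
ASV_0056	Phylum_C;Class_1;Order_1;Family_1;ASV_0056_genus
ASV_0057	Phylum_C;Class_2;Order_2;Family_2;ASV_0057_genus
ASV_0058	Phylum_D;Class_0;Order_0;Family_0;ASV_0058_genus
ASV_0059	Phylum_D;Class_1;Order_1;Family_1;ASV_0059_genus
ASV_0060	Phylum_D;Class_2;Order_2;Family_2;ASV_0060_genus
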