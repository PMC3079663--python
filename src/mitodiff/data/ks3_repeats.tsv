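id	type	size	copies	difference	identity
R1	IR	98977	63707-162682;520734-421758	copy-1 1 bp del.; 3 bp mismatch	99.99
R2	DR	64991	285968-350958;357152-422142	identical	100
R3	IR/DR	33605	596378-629979;497569-463965;86872-120476	copy-1 4 bp del.; 20 bp mismatch	99.93
R4	DR	28476	563639-592113;514143-542618	copy-1 1 bp del.; 3 bp mismatch	99.99
R5	IR	8853	217390-226242;521779-512927	2 bp mismatch	99.98
R6	DR/IR	7808	218435-226242;63707-71514;520734-512927	3 bp mismatch	99.96
R7	IR/DR	7637	563639-571274;225026-217390;514143-521779	copy-1 1 bp del.; 3 bp mismatch	99.97
R8	IR/DR	6592	563639-570299;70298-63707;514143-520734;225026-218435	copy-1 1 bp del.; 4 bp mismatch	99.92
R9	DR	4645	233766-238410;592108-596752	3 bp mismatch	99.94
R10	DR	442	238110-238550;389430-389871;318246-318687	copy-1 1 bp del.; 7 bp mismatch	98.19
R11	IR	409	178030-178438;532798-532390;582293-581885	identical	100
R12	IR	385	162298-162682;350958-350574;422142-421758	identical	100
R13	DR/IR	391	15949-16326;570623-571013;218041-217651;521128-521518	copy-1 13 bp del.; 26 bp mismatch	90.03
R14	IR/DR	378	238036-238410;497569-497192;86872-87249;596378-596752	copy-1 4 bp del.; 20 bp mismatch	93.4
R15	DR/IR	352	86898-87249;318195-318546;389379-389730;497543-497192;238062-238410;596404-596752	copy-1 1 bp del.; copy-5 4 bp del.; 20 bp mismatch	93.1
R16	IR/DR	295	42766-43060;126790-126496;457651-457945	identical	100
R17	DR/IR	275	67932-68206;114585-114859;624088-624362;469856-469582;222660-222934;566004-565730;516509-516235	identical	100
R18	IR	246	2411-2646;416690-416445;345506-345261	copy-1 10 bp del.; 5 bp mismatch	94.31
R19	DR/IR	201	546169-546367;435151-435351;149290-149090	copy-1 2 bp del.; 2 bp mismatch	98.01
R20	DR	197	182981-183177;543334-543530	1 bp mismatch	99.49
R21	IR/DR	193	265694-265885;610987-610795;482957-483149;101484-101292	copy-1 1 bp del.; 1 bp mismatch	98.96
R22	IR	190	13994-14183;63634-63445	4 bp mismatch	97.89
R23	IR	189	271802-271990;420288-420100;349104-348916	identical	100
R24	DR	185	13588-13772;358007-358191;286823-287007	identical	100
R25	DR/IR	179	301013-301190;643373-643195;372197-372374	copy-1,3 1 bp del.; 9 bp mismatch	94.41
R26	DR	154	260325-260478;642452-642605	4 bp mismatch	97.4
R27	DR/IR	154	91917-92070;170372-170525;492524-492371;601420-601573	8 bp mismatch	94.81
R28	DR	145	37571-37703;543007-543151	copy-1 12 bp del.; 2 bp mismatch	90.34
R29	IR/DR	119	529005-529122;349116-348998;420300-420182;578500-578617	copy-1,4 1 bp del.; 2 bp mismatch	97.48
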